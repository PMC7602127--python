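"""Reading and writing LC-MS(/MS) runs and tabular artifacts.

Coordinate conventions used throughout the package are fixed here:

* scans are 0-indexed in retention-time order;
* m/z is in Thomson, intensities are unitless and non-negative;
* retention time is carried in a user-selected variant — minutes (the
  default), seconds, or the bare scan index;
* peak lists are stored centroided and sorted ascending by m/z.

Runs are read from mzXML or mzML (centroided) via :mod:`pyteomics`; a
minimal standards-conformant mzXML writer is provided so that simulated
datasets can round-trip through the same reader as real data.
"""

from __future__ import annotations

import base64
import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mzml, mzxml

from .bucket import BucketTable
from .errors import EmptyRunError, ParseError, ValidationError

RT_VARIANTS = ("minutes", "seconds", "scan_index")


@dataclass
class Scan:
    """One centroided mass spectrum.

    ``precursor_mz`` must be present exactly when ``ms_level == 2``.
    """

    scan_index: int
    ms_level: int
    rt: float
    mz_values: np.ndarray
    intensities: np.ndarray
    precursor_mz: float | None = None
    precursor_intensity: float | None = None

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_values.shape != self.intensities.shape:
            raise ValidationError(
                f"scan {self.scan_index}: m/z and intensity lengths differ"
            )
        if self.mz_values.size and np.any(np.diff(self.mz_values) <= 0):
            raise ValidationError(
                f"scan {self.scan_index}: m/z values not strictly ascending"
            )
        if self.intensities.size and (self.intensities < 0).any():
            raise ValidationError(f"scan {self.scan_index}: negative intensity")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValidationError(
                f"scan {self.scan_index}: MS2 scan without precursor m/z"
            )

    @property
    def n_peaks(self) -> int:
        return int(self.mz_values.size)


@dataclass
class RunData:
    """An ordered collection of scans from one sample."""

    sample_id: str
    rt_variant: str
    scans: list[Scan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.rt_variant not in RT_VARIANTS:
            raise ValidationError(
                f"rt_variant must be one of {RT_VARIANTS}, got {self.rt_variant!r}"
            )
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValidationError(
                f"run {self.sample_id}: scan rt values are not non-decreasing"
            )

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def scans_at_level(self, ms_level: int) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == ms_level]


def _rt_minutes_from_mzml(scan_dict: dict) -> float:
    entry = scan_dict["scanList"]["scan"][0]["scan start time"]
    unit = getattr(entry, "unit_info", "minute")
    rt = float(entry)
    return rt / 60.0 if unit and "second" in str(unit) else rt


def _iter_mzxml(path: str):
    with mzxml.read(path) as reader:
        for s in reader:
            precursor_mz = precursor_int = None
            if s.get("precursorMz") is not None:
                p = s["precursorMz"]
                if isinstance(p, list):
                    p = p[0]
                if isinstance(p, dict):
                    precursor_mz = float(p["precursorMz"])
                    if p.get("precursorIntensity") is not None:
                        precursor_int = float(p["precursorIntensity"])
                else:
                    precursor_mz = float(p)
            # pyteomics normalizes mzXML retentionTime to minutes
            yield (
                int(s["msLevel"]),
                float(s["retentionTime"]),
                s["m/z array"],
                s["intensity array"],
                precursor_mz,
                precursor_int,
            )


def _iter_mzml(path: str):
    with mzml.read(path) as reader:
        for s in reader:
            precursor_mz = precursor_int = None
            if "precursorList" in s:
                ion = s["precursorList"]["precursor"][0]["selectedIonList"][
                    "selectedIon"
                ][0]
                precursor_mz = float(ion["selected ion m/z"])
                if "peak intensity" in ion:
                    precursor_int = float(ion["peak intensity"])
            yield (
                int(s["ms level"]),
                _rt_minutes_from_mzml(s),
                s["m/z array"],
                s["intensity array"],
                precursor_mz,
                precursor_int,
            )


def read_run(
    path,
    rt_variant: str = "minutes",
    ms_levels: set[int] | frozenset[int] = frozenset({1, 2}),
    sample_id: str | None = None,
) -> RunData:
    """Read an mzXML/mzML file into a :class:`RunData`.

    Only scans whose MS level is in ``ms_levels`` are kept; retention times
    are converted to the requested variant; the sample id defaults to the
    file stem. Scans come out sorted by rt (ties by original order) with
    peaks sorted ascending by m/z.
    """
    path = Path(path)
    if rt_variant not in RT_VARIANTS:
        raise ValidationError(
            f"rt_variant must be one of {RT_VARIANTS}, got {rt_variant!r}"
        )
    suffix = path.suffix.lower()
    if suffix == ".mzxml":
        iterator = _iter_mzxml
    elif suffix == ".mzml":
        iterator = _iter_mzml
    else:
        raise ParseError(f"{path}: unrecognized extension {suffix!r}")

    raw: list[tuple] = []
    try:
        for rec in iterator(str(path)):
            raw.append(rec)
    except (OSError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: cannot read file ({exc})") from exc
    except Exception as exc:  # pyteomics raises format-specific errors
        raise ParseError(f"{path}: failed to parse ({exc})") from exc

    kept = [r for r in raw if r[0] in ms_levels]
    if not kept:
        raise EmptyRunError(
            f"{path}: no scans at MS level(s) {sorted(ms_levels)}"
        )
    kept.sort(key=lambda r: r[1])  # stable: rt order, ties by file order

    scans = []
    for idx, (level, rt_min, mz, inten, pmz, pint) in enumerate(kept):
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if rt_variant == "minutes":
            rt = rt_min
        elif rt_variant == "seconds":
            rt = rt_min * 60.0
        else:
            rt = float(idx)
        scans.append(
            Scan(
                scan_index=idx,
                ms_level=level,
                rt=rt,
                mz_values=mz,
                intensities=inten,
                precursor_mz=pmz,
                precursor_intensity=pint,
            )
        )
    return RunData(sample_id=sample_id or path.stem, rt_variant=rt_variant, scans=scans)


def _rt_to_seconds(rt: float, rt_variant: str) -> float:
    # scan_index rt is written on the minutes scale so values survive
    # a round trip under the same variant selection
    if rt_variant == "seconds":
        return rt
    return rt * 60.0


def _encode_peaks(mz: np.ndarray, inten: np.ndarray) -> str:
    interleaved = np.empty(mz.size * 2, dtype=">f8")
    interleaved[0::2] = mz
    interleaved[1::2] = inten
    return base64.b64encode(interleaved.tobytes()).decode("ascii")


def write_run(run: RunData, path) -> Path:
    """Write a :class:`RunData` as a minimal mzXML file.

    Peaks are encoded uncompressed as network-order 64-bit pairs, which the
    :mod:`pyteomics` reader (and any conformant consumer) accepts;
    ``read_run(write_run(run))`` reproduces scan count, levels, rt and peak
    lists to well below 1e-6 absolute/relative.
    """
    path = Path(path)
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{run.n_scans}">',
    ]
    for scan in run.scans:
        rt_s = _rt_to_seconds(scan.rt, run.rt_variant)
        lines.append(
            f'  <scan num="{scan.scan_index + 1}" msLevel="{scan.ms_level}"'
            f' retentionTime="PT{rt_s:.6f}S" peaksCount="{scan.n_peaks}">'
        )
        if scan.ms_level == 2:
            # precursorIntensity is a required attribute in the mzXML schema
            pint = scan.precursor_intensity or 0.0
            lines.append(
                f'   <precursorMz precursorIntensity="{pint:.6f}">'
                f"{scan.precursor_mz:.6f}</precursorMz>"
            )
        payload = _encode_peaks(scan.mz_values, scan.intensities)
        lines.append(
            '   <peaks precision="64" byteOrder="network" contentType="m/z-int"'
            f' compressionType="none" compressedLen="0">{payload}</peaks>'
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    try:
        path.write_text("\n".join(lines))
    except OSError as exc:
        raise ParseError(f"{path}: cannot write file ({exc})") from exc
    return path


def read_bucket_table(path) -> BucketTable:
    """Read a samples × features CSV into a :class:`BucketTable`.

    First column holds sample ids; remaining columns are feature keys. Blank
    cells mean "feature absent" and are imputed as 0; non-numeric cells and
    duplicate sample ids are rejected with the offending location named.
    """
    path = Path(path)
    try:
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
    except OSError as exc:
        raise ParseError(f"{path}: cannot read file ({exc})") from exc
    if not rows or len(rows[0]) < 1:
        raise ParseError(f"{path}: empty bucket table")
    header = rows[0][1:]
    sample_ids: list[str] = []
    matrix: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        sample_ids.append(row[0])
        values = []
        for j, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            if cell == "":
                values.append(0.0)
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row {i}, column {j} ({cell!r})"
                ) from None
        if len(values) != len(header):
            raise ParseError(f"{path}: row {i} has {len(values)} cells, expected {len(header)}")
        matrix.append(values)
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample ids {dupes}")
    frame = pd.DataFrame(matrix, index=sample_ids, columns=header, dtype=float)
    return BucketTable(frame)
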