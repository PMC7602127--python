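"""MS2 analog-family pipeline: precursor binning, diagnostic-fragment
filtering, scan clustering and consensus spectra.

Families of structural analogs (e.g. a natural-product scaffold decorated
with variable acyl side chains) share core fragment ions while differing in
their precursor masses. The pipeline exploits this: MS2 scans are binned by
rounded precursor m/z, bins are kept only if some member scan carries the
diagnostic core fragment, scans within each retained bin are clustered by
cosine distance on coarsely vectorized fragment spectra (separating
co-isolated isomers or chimeric scans), and each cluster is summarized as a
consensus spectrum for manual interpretation.

Everything is a pure function of its inputs — no randomness — so repeated
runs are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .errors import EmptyRunError, ValidationError
from .msio import RunData, Scan

__all__ = [
    "Ms2Params",
    "PrecursorBin",
    "ConsensusSpectrum",
    "bin_by_precursor",
    "filter_bins_by_fragment",
    "scan_cosine_distance",
    "cluster_scans",
    "consensus_spectrum",
    "run_ms2_pipeline",
    "consensus_to_mgf",
]


@dataclass(frozen=True)
class Ms2Params:
    """Parameters of the MS2 family pipeline.

    bin_decimals : decimal places for rounding precursor m/z into bins
        (0 = unit-mass bins, matching low-resolution ion-trap data).
    fragment_filter_mz / fragment_tol : the diagnostic fragment and the Da
        window used to keep a precursor bin.
    cluster_cutoff : cosine-distance height at which the within-bin scan
        dendrogram is cut.
    fragment_bin_width : Da width of the fixed grid used to vectorize
        fragment spectra for cosine comparison.
    consensus_min_fraction : fraction of a cluster's scans a fragment bin
        must appear in to enter the consensus spectrum.
    """

    bin_decimals: int = 0
    fragment_filter_mz: float = 168.0
    fragment_tol: float = 0.5
    cluster_cutoff: float = 0.15
    fragment_bin_width: float = 1.0
    consensus_min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0:
            raise ValidationError("fragment_tol must be > 0")
        if not 0 <= self.cluster_cutoff <= 1:
            raise ValidationError("cluster_cutoff must be in [0, 1]")
        if self.fragment_bin_width <= 0:
            raise ValidationError("fragment_bin_width must be > 0")
        if not 0 < self.consensus_min_fraction <= 1:
            raise ValidationError("consensus_min_fraction must be in (0, 1]")


@dataclass
class PrecursorBin:
    """All MS2 scans whose rounded precursor m/z share one key."""

    bin_key: float
    scans: list[Scan] = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return len(self.scans)


@dataclass
class ConsensusSpectrum:
    """Representative fragment spectrum for one cluster of MS2 scans.

    ``peaks`` rows are (mean m/z, mean relative intensity, member fraction),
    intensities normalized so the base peak is 1.
    """

    bin_key: float
    cluster_id: int
    n_members: int
    peaks: list[tuple[float, float, float]]

    def has_fragment(self, mz: float, tol: float) -> bool:
        return any(abs(p[0] - mz) <= tol for p in self.peaks)


def _round_half_up(x: float, decimals: int) -> float:
    scale = 10.0 ** decimals
    return math.floor(x * scale + 0.5) / scale


def bin_by_precursor(scans: list[Scan], bin_decimals: int = 0) -> list[PrecursorBin]:
    """Partition MS2 scans by precursor m/z rounded half-up.

    ``bin_decimals = 0`` gives nearest-integer (unit mass) bins. Bins come
    out sorted by key; scans keep their input order within a bin.
    """
    bins: dict[float, PrecursorBin] = {}
    for scan in scans:
        if scan.ms_level != 2:
            raise ValidationError(
                f"scan {scan.scan_index} is MS{scan.ms_level}, expected MS2"
            )
        key = _round_half_up(scan.precursor_mz, bin_decimals)
        bins.setdefault(key, PrecursorBin(bin_key=key)).scans.append(scan)
    return [bins[k] for k in sorted(bins)]


def filter_bins_by_fragment(
    bins: list[PrecursorBin], fragment_mz: float, tol: float
) -> list[PrecursorBin]:
    """Keep bins in which ≥ 1 member scan has a peak within tol of fragment_mz."""
    if tol <= 0:
        raise ValidationError("fragment tolerance must be > 0")
    kept = []
    for b in bins:
        for scan in b.scans:
            lo = np.searchsorted(scan.mz_values, fragment_mz - tol, side="left")
            hi = np.searchsorted(scan.mz_values, fragment_mz + tol, side="right")
            if hi > lo:
                kept.append(b)
                break
    return kept


def _vectorize(scan: Scan, bin_width: float) -> dict[int, float]:
    vec: dict[int, float] = {}
    for mz, inten in zip(scan.mz_values, scan.intensities):
        idx = int(mz // bin_width)
        vec[idx] = vec.get(idx, 0.0) + float(inten)
    return vec


def scan_cosine_distance(a: Scan, b: Scan, fragment_bin_width: float = 1.0) -> float:
    """1 − cosine similarity of two fragment spectra on a fixed m/z grid.

    Peaks are accumulated into bins of ``fragment_bin_width`` anchored at
    m/z 0 before comparison, making the measure robust to unit-resolution
    mass jitter.
    """
    for scan in (a, b):
        if scan.n_peaks == 0:
            raise ValidationError(f"scan {scan.scan_index} has no peaks")
    va, vb = _vectorize(a, fragment_bin_width), _vectorize(b, fragment_bin_width)
    dot = sum(v * vb.get(k, 0.0) for k, v in va.items())
    na = math.sqrt(sum(v * v for v in va.values()))
    nb = math.sqrt(sum(v * v for v in vb.values()))
    if na == 0 or nb == 0:
        raise ValidationError("zero-intensity scan in cosine distance")
    return max(0.0, 1.0 - dot / (na * nb))


def cluster_scans(
    bin_: PrecursorBin, cutoff: float, fragment_bin_width: float = 1.0
) -> list[list[Scan]]:
    """Cut the average-linkage scan dendrogram of one bin at ``cutoff``.

    Returns clusters (lists of scans, input order preserved) that partition
    the bin; a singleton bin yields one singleton cluster.
    """
    scans = bin_.scans
    if not scans:
        raise ValidationError(f"bin {bin_.bin_key}: empty")
    if len(scans) == 1:
        return [[scans[0]]]
    n = len(scans)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = scan_cosine_distance(
                scans[i], scans[j], fragment_bin_width
            )
    merge = sch.linkage(squareform(dist, checks=False), method="average")
    labels = sch.fcluster(merge, t=cutoff, criterion="distance")
    clusters: dict[int, list[Scan]] = {}
    for scan, lab in zip(scans, labels):
        clusters.setdefault(int(lab), []).append(scan)
    # order clusters by first member's position for determinism
    first_pos = {
        lab: min(i for i, l in enumerate(labels) if l == lab) for lab in clusters
    }
    return [clusters[lab] for lab in sorted(clusters, key=lambda l: first_pos[l])]


def consensus_spectrum(
    cluster: list[Scan],
    fragment_bin_width: float = 1.0,
    min_fraction: float = 0.5,
    bin_key: float = float("nan"),
    cluster_id: int = 0,
) -> ConsensusSpectrum:
    """Aggregate a cluster of MS2 scans into one consensus spectrum.

    Fragment bins present in at least ``min_fraction`` of the member scans
    are retained; each retained peak's m/z is the intensity-weighted mean
    of the contributing centroids and its intensity the mean of the
    per-scan relative intensities, renormalized to base peak 1.
    """
    if not cluster:
        raise ValidationError("empty cluster")
    n = len(cluster)
    support: dict[int, int] = {}
    wmz: dict[int, float] = {}
    weight: dict[int, float] = {}
    rel_sum: dict[int, float] = {}
    for scan in cluster:
        base = float(scan.intensities.max()) if scan.n_peaks else 0.0
        if base <= 0:
            raise ValidationError(f"scan {scan.scan_index} has no positive peaks")
        per_bin: dict[int, float] = {}
        for mz, inten in zip(scan.mz_values, scan.intensities):
            idx = int(mz // fragment_bin_width)
            per_bin[idx] = per_bin.get(idx, 0.0) + float(inten)
            wmz[idx] = wmz.get(idx, 0.0) + float(inten) * float(mz)
            weight[idx] = weight.get(idx, 0.0) + float(inten)
        for idx, summed in per_bin.items():
            support[idx] = support.get(idx, 0) + 1
            rel_sum[idx] = rel_sum.get(idx, 0.0) + summed / base
    peaks = []
    for idx in sorted(support):
        frac = support[idx] / n
        if frac >= min_fraction and weight[idx] > 0:
            peaks.append((wmz[idx] / weight[idx], rel_sum[idx] / n, frac))
    if peaks:
        top = max(p[1] for p in peaks)
        peaks = [(mz, inten / top, frac) for mz, inten, frac in peaks]
    return ConsensusSpectrum(
        bin_key=bin_key, cluster_id=cluster_id, n_members=n, peaks=peaks
    )


def run_ms2_pipeline(
    runs: list[RunData], params: Ms2Params
) -> tuple[list[ConsensusSpectrum], pd.DataFrame]:
    """Full pipeline: bin → diagnostic filter → cluster → consensus.

    Returns the consensus spectra and a per-bin summary report
    (bin_key, n_scans, n_clusters, n_consensus_peaks).
    """
    scans = [s for run in runs for s in run.scans_at_level(2)]
    if not scans:
        raise EmptyRunError("no MS2 scans in input runs")
    bins = bin_by_precursor(scans, params.bin_decimals)
    kept = filter_bins_by_fragment(
        bins, params.fragment_filter_mz, params.fragment_tol
    )
    consensus: list[ConsensusSpectrum] = []
    rows = []
    for b in kept:
        clusters = cluster_scans(b, params.cluster_cutoff, params.fragment_bin_width)
        n_peaks = 0
        for cid, cluster in enumerate(clusters):
            spec = consensus_spectrum(
                cluster,
                params.fragment_bin_width,
                params.consensus_min_fraction,
                bin_key=b.bin_key,
                cluster_id=cid,
            )
            consensus.append(spec)
            n_peaks += len(spec.peaks)
        rows.append(
            {
                "bin_key": b.bin_key,
                "n_scans": b.n_scans,
                "n_clusters": len(clusters),
                "n_consensus_peaks": n_peaks,
            }
        )
    report = pd.DataFrame(
        rows, columns=["bin_key", "n_scans", "n_clusters", "n_consensus_peaks"]
    )
    return consensus, report


def consensus_to_mgf(spectra: list[ConsensusSpectrum]) -> str:
    """Render consensus spectra as MGF text (PEPMASS = precursor bin key)."""
    blocks = []
    for spec in spectra:
        lines = [
            "BEGIN IONS",
            f"TITLE=bin{spec.bin_key:g}_cluster{spec.cluster_id}_n{spec.n_members}",
            f"PEPMASS={spec.bin_key:.6f}",
            "CHARGE=1+",
        ]
        lines += [f"{mz:.6f} {inten:.6f}" for mz, inten, _frac in spec.peaks]
        lines.append("END IONS")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")
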