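"""MS1 chromatographic feature detection, consolidation and transforms.

The detector follows a deterministic greedy scheme:

1. **Trace building** (:func:`extract_eics`): scans are walked in rt order
   and every centroid joins the open extracted-ion-chromatogram trace whose
   running intensity-weighted mean m/z is nearest within ``mz_tol`` (ties go
   to the lower-m/z trace), otherwise it opens a new trace. A trace closes
   after ``max_gap_scans`` consecutive scans without a member. Every input
   centroid ends up in exactly one trace.
2. **Peak picking** (:func:`detect_features`): within each trace, local
   maxima at or above ``min_height`` become apices; peak boundaries extend
   outward until intensity drops below ``edge_frac`` × apex, a local
   minimum separating two apices is reached (the peak is split there), or
   the trace ends. Peaks spanning fewer than ``min_scans`` points are
   discarded. The integration value is the trapezoidal area over rt and the
   feature m/z is the intensity-weighted mean over the peak's points.
3. **Consolidation** (:func:`consolidate`): features from all samples are
   pooled and greedily clustered, highest area first, into bucket-table
   columns; each column takes at most one feature per sample (the
   highest-area one within the m/z and rt tolerances of the seed).

Every rule is deterministic, so repeated runs are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bucket import BucketTable, make_key
from .errors import EmptyRunError, UsageError, ValidationError
from .msio import RunData

__all__ = [
    "DetectionParams",
    "MS1Feature",
    "extract_eics",
    "detect_features",
    "consolidate",
    "transform",
    "features_to_frame",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the MS1 feature detector.

    mz_tol : Da, EIC association tolerance.
    rt_tol : rt units, apex merge tolerance (used at consolidation).
    min_height : minimum apex intensity for a peak.
    min_scans : minimum number of points a peak must span.
    max_gap_scans : consecutive scans a trace survives without a member.
    edge_frac : peak boundary cut at ``edge_frac`` × apex intensity.
    """

    mz_tol: float = 0.01
    rt_tol: float = 0.2
    min_height: float = 0.0
    min_scans: int = 3
    max_gap_scans: int = 1
    edge_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.mz_tol <= 0:
            raise ValidationError("mz_tol must be > 0")
        if self.rt_tol < 0:
            raise ValidationError("rt_tol must be >= 0")
        if self.min_height < 0:
            raise ValidationError("min_height must be >= 0")
        if self.min_scans < 1:
            raise ValidationError("min_scans must be >= 1")
        if self.max_gap_scans < 0:
            raise ValidationError("max_gap_scans must be >= 0")
        if not 0 < self.edge_frac <= 1:
            raise ValidationError("edge_frac must be in (0, 1]")


@dataclass
class MS1Feature:
    """An integrated chromatographic peak from one sample."""

    sample_id: str
    mz: float
    rt_apex: float
    rt_start: float
    rt_end: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if not self.rt_start <= self.rt_apex <= self.rt_end:
            raise ValidationError("feature rt bounds must bracket the apex")
        if self.area <= 0:
            raise ValidationError("feature area must be > 0")


class _Trace:
    __slots__ = ("points", "weight_sum", "wmz_sum", "last_scan")

    def __init__(self, scan_index: int, rt: float, mz: float, intensity: float):
        self.points: list[tuple[int, float, float, float]] = [
            (scan_index, rt, mz, intensity)
        ]
        w = max(intensity, 1e-300)
        self.weight_sum = w
        self.wmz_sum = w * mz
        self.last_scan = scan_index

    @property
    def centroid(self) -> float:
        return self.wmz_sum / self.weight_sum

    def add(self, scan_index: int, rt: float, mz: float, intensity: float) -> None:
        self.points.append((scan_index, rt, mz, intensity))
        w = max(intensity, 1e-300)
        self.weight_sum += w
        self.wmz_sum += w * mz
        self.last_scan = scan_index


def extract_eics(
    run: RunData, params: DetectionParams
) -> list[list[tuple[int, float, float, float]]]:
    """Partition a run's MS1 centroids into EIC traces.

    Returns a list of traces, each a list of ``(scan_index, rt, mz,
    intensity)`` points in scan order, ordered by first appearance.
    """
    ms1_scans = run.scans_at_level(1)
    if not ms1_scans:
        raise EmptyRunError(f"run {run.sample_id}: no MS1 scans")

    open_traces: list[_Trace] = []
    closed: list[_Trace] = []
    for pos, scan in enumerate(ms1_scans):
        if open_traces:
            # gap counted in MS1 scan positions, so interleaved MS2 scans
            # do not break trace continuity
            survivors = []
            for tr in open_traces:
                if pos - tr.last_scan > params.max_gap_scans + 1:
                    closed.append(tr)
                else:
                    survivors.append(tr)
            open_traces = survivors
        centroids = np.array([tr.centroid for tr in open_traces])
        for mz, inten in zip(scan.mz_values, scan.intensities):
            if centroids.size:
                dist = np.abs(centroids - mz)
                best = dist.min()
                if best <= params.mz_tol:
                    # nearest wins; ties resolved toward the lower-m/z trace
                    tied = np.flatnonzero(dist <= best + 1e-12)
                    idx = int(tied[np.argmin(centroids[tied])])
                    open_traces[idx].add(pos, scan.rt, mz, inten)
                    centroids[idx] = open_traces[idx].centroid
                    continue
            tr = _Trace(pos, scan.rt, mz, inten)
            open_traces.append(tr)
            centroids = np.append(centroids, tr.centroid)
    closed.extend(open_traces)
    closed.sort(key=lambda tr: (tr.points[0][0], tr.points[0][2]))
    return [tr.points for tr in closed]


def _pick_peaks(intensities: np.ndarray, params: DetectionParams) -> list[tuple[int, int, int]]:
    """Find (left, apex, right) index triples inside one trace."""
    n = intensities.size
    # plateau-safe local maxima: first index of each maximal plateau
    apices = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and intensities[j + 1] == intensities[i]:
            j += 1
        left = intensities[i - 1] if i > 0 else -np.inf
        right = intensities[j + 1] if j + 1 < n else -np.inf
        if intensities[i] > left and intensities[i] > right:
            apices.append(i)
        i = j + 1
    apices = [a for a in apices if intensities[a] >= params.min_height]
    if not apices:
        return []

    # split points: the (first) minimum between consecutive apices
    splits = []
    for a, b in zip(apices, apices[1:]):
        seg = intensities[a : b + 1]
        splits.append(a + int(np.argmin(seg)))

    peaks = []
    for k, apex in enumerate(apices):
        lo_bound = splits[k - 1] if k > 0 else 0
        hi_bound = splits[k] if k < len(splits) else n - 1
        cut = params.edge_frac * intensities[apex]
        left = apex
        while left > lo_bound and intensities[left - 1] >= cut:
            left -= 1
        right = apex
        while right < hi_bound and intensities[right + 1] >= cut:
            right += 1
        peaks.append((left, apex, right))
    return peaks


def detect_features(run: RunData, params: DetectionParams) -> list[MS1Feature]:
    """Detect and integrate MS1 features in one run.

    See the module docstring for the full algorithm. Returned features are
    sorted by (rt_apex, mz).
    """
    traces = extract_eics(run, params)
    features: list[MS1Feature] = []
    for points in traces:
        rts = np.array([p[1] for p in points])
        mzs = np.array([p[2] for p in points])
        intens = np.array([p[3] for p in points])
        for left, apex, right in _pick_peaks(intens, params):
            if right - left + 1 < params.min_scans:
                continue
            seg = slice(left, right + 1)
            area = float(np.trapezoid(intens[seg], rts[seg]))
            if area <= 0:
                continue
            w = intens[seg]
            wsum = w.sum()
            mz = float((w * mzs[seg]).sum() / wsum) if wsum > 0 else float(mzs[apex])
            features.append(
                MS1Feature(
                    sample_id=run.sample_id,
                    mz=mz,
                    rt_apex=float(rts[apex]),
                    rt_start=float(rts[left]),
                    rt_end=float(rts[right]),
                    height=float(intens[apex]),
                    area=area,
                )
            )
    features.sort(key=lambda f: (f.rt_apex, f.mz))
    return features


def consolidate(
    features_by_sample: dict[str, list[MS1Feature]],
    mz_tol: float,
    rt_tol: float,
) -> BucketTable:
    """Merge per-sample features into a samples × features bucket table.

    Greedy, highest-area-first clustering: the largest unassigned feature
    seeds a column and absorbs, from each sample, that sample's largest
    unassigned feature lying within ``mz_tol`` and ``rt_tol`` of the seed.
    The column key is the intensity(area)-weighted mean (m/z, rt) of the
    members. Cells of samples that contributed nothing are 0.
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise ValidationError("consolidation tolerances must be > 0")
    if not features_by_sample:
        raise ValidationError("need at least one sample")
    sample_ids = list(features_by_sample)

    pool: list[tuple[str, MS1Feature]] = [
        (sid, f) for sid, feats in features_by_sample.items() for f in feats
    ]
    # seed order: area desc, ties toward lower m/z then lower rt
    order = sorted(
        range(len(pool)),
        key=lambda i: (-pool[i][1].area, pool[i][1].mz, pool[i][1].rt_apex),
    )
    assigned = [False] * len(pool)
    by_sample_sorted: dict[str, list[int]] = {sid: [] for sid in sample_ids}
    for i in order:
        by_sample_sorted[pool[i][0]].append(i)

    columns: list[tuple[float, float, dict[str, float]]] = []
    for seed_idx in order:
        if assigned[seed_idx]:
            continue
        seed_sample, seed = pool[seed_idx]
        members: list[int] = []
        for sid in sample_ids:
            if sid == seed_sample:
                continue  # the seed already fills its own sample's cell
            for i in by_sample_sorted[sid]:
                if assigned[i]:
                    continue
                f = pool[i][1]
                if abs(f.mz - seed.mz) <= mz_tol and abs(f.rt_apex - seed.rt_apex) <= rt_tol:
                    members.append(i)
                    break
        members.append(seed_idx)
        for i in members:
            assigned[i] = True
        feats = [pool[i][1] for i in members]
        weights = np.array([f.area for f in feats])
        mz_c = float(np.average([f.mz for f in feats], weights=weights))
        rt_c = float(np.average([f.rt_apex for f in feats], weights=weights))
        cells = {pool[i][0]: pool[i][1].area for i in members}
        columns.append((mz_c, rt_c, cells))

    columns.sort(key=lambda c: (c[0], c[1]))
    data = {
        make_key(mz_c, rt_c): [cells.get(sid, 0.0) for sid in sample_ids]
        for mz_c, rt_c, cells in columns
    }
    frame = pd.DataFrame(data, index=sample_ids, dtype=float)
    coords = {make_key(mz_c, rt_c): (mz_c, rt_c) for mz_c, rt_c, _ in columns}
    return BucketTable(frame, feature_coords=coords)


def transform(table: BucketTable, method: str) -> BucketTable:
    """Apply an elementwise/rowwise transformation to a bucket table.

    ``raw`` is the identity; ``log10p1`` is log10(x+1); ``tic`` divides each
    row by its sum (all-zero rows stay zero); ``presence_absence`` maps
    positive cells to 1.
    """
    values = table.values.copy()
    if method == "raw":
        pass
    elif method == "log10p1":
        values = np.log10(values + 1.0)
    elif method == "tic":
        sums = values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(sums > 0, values / np.where(sums > 0, sums, 1.0), 0.0)
    elif method == "presence_absence":
        values = (values > 0).astype(float)
    else:
        raise UsageError(f"unknown transform method {method!r}")
    frame = pd.DataFrame(
        values, index=table.data.index, columns=table.data.columns, dtype=float
    )
    return BucketTable(frame, transform_tag=method, feature_coords=dict(table.feature_coords))


def features_to_frame(features: list[MS1Feature]) -> pd.DataFrame:
    """Tabulate detected features for CSV export."""
    return pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "mz": f.mz,
                "rt_apex": f.rt_apex,
                "rt_start": f.rt_start,
                "rt_end": f.rt_end,
                "height": f.height,
                "area": f.area,
            }
            for f in features
        ],
        columns=["sample_id", "mz", "rt_apex", "rt_start", "rt_end", "height", "area"],
    )
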