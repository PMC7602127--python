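"""Synthetic LC-MS(/MS) dataset generator with known ground truth.

The generator emulates the structure of a chemogeographic field study:
several sample groups (collection regions), metabolites shared by all
groups plus group-specific metabolites, Gaussian chromatographic elution
profiles over a uniform scan grid with additive baseline noise, per-sample
feature dropout, and — for the MS2 side — an analog family whose members
share diagnostic core fragment ions while decoy precursors lack them.

Everything is drawn from a single seeded random stream in a fixed,
documented order (features, then samples in order, then per-scan noise),
so a fixed seed reproduces files byte-for-byte. What the simulator does
*not* emulate: chromatographic tailing, mass-accuracy drift, isotope
envelopes and adducts (an optional flag adds +1.00335 isotopologue peaks
for stress testing), matrix effects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .msio import RunData, Scan

__all__ = [
    "SimConfig",
    "Ms2FamilyConfig",
    "GroundTruth",
    "simulate_ms1_dataset",
    "simulate_ms2_dataset",
]

#: mass difference of the +1 isotopologue (13C − 12C), Da
_ISOTOPE_SPACING = 1.00335


@dataclass(frozen=True)
class Ms2FamilyConfig:
    """Planted MS2 analog family plus decoy precursors."""

    n_analogs: int = 5
    core_fragments: tuple[float, ...] = (168.10, 110.07)
    side_fragments_per_analog: int = 3
    n_decoy_precursors: int = 20
    replicates_per_precursor: int = 4
    intensity_jitter: float = 0.10
    precursor_mz_range: tuple[float, float] = (350.0, 800.0)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults describe the benchmark chemogeographic design used throughout
    the test-suite: 5 regions × 3 samples, 30 shared + 10 region-specific
    features per region, 200 scans over a 12-minute gradient, Gaussian
    peaks of σ = 3 scan intervals, apex intensities 1e5–1e6 against
    baseline noise of sd 1e3 (signal-to-baseline ≥ 100), and 5% feature
    dropout per sample.
    """

    seed: int = 0
    n_groups: int = 5
    samples_per_group: int = 3
    shared_features: int = 30
    specific_features_per_group: int = 10
    mz_range: tuple[float, float] = (150.0, 900.0)
    rt_range: tuple[float, float] = (0.0, 12.0)
    peak_sigma_scans: float = 3.0
    apex_intensity_range: tuple[float, float] = (1e5, 1e6)
    baseline_noise_sd: float = 1e3
    dropout_prob: float = 0.05
    scans_per_run: int = 200
    noise_peaks_per_scan: int = 8
    mz_jitter_sd: float = 0.001
    min_mz_spacing: float = 0.05
    add_isotopes: bool = False
    ms2_family: Ms2FamilyConfig | None = None

    def __post_init__(self) -> None:
        for name in ("n_groups", "samples_per_group", "shared_features",
                     "specific_features_per_group", "scans_per_run"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ValidationError("dropout_prob must be in [0, 1)")
        for name in ("mz_range", "rt_range", "apex_intensity_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be a non-degenerate interval")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """What was actually planted, for scoring detectors against.

    ``features`` has one row per emitted peak instance (group, sample, mz,
    rt, true_area) where ``true_area`` is the trapezoidal integral of the
    emitted (noise-included) intensities of that peak's points over rt.
    ``catalog`` lists the planted feature definitions; ``groups`` maps
    sample id → group label; ``ms2_families`` lists planted precursors.
    """

    features: pd.DataFrame
    catalog: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    ms2_families: pd.DataFrame | None = None


def _place_mz(rng: np.random.Generator, n: int, mz_range, spacing: float) -> np.ndarray:
    lo, hi = mz_range
    if n * spacing > (hi - lo):
        raise ValidationError(
            f"cannot place {n} features with {spacing} Da spacing in {mz_range}"
        )
    placed: list[float] = []
    attempts = 0
    while len(placed) < n:
        mz = float(rng.uniform(lo, hi))
        if all(abs(mz - p) >= spacing for p in placed):
            placed.append(mz)
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise ValidationError(
                "infeasible config: could not place resolvable feature m/z values"
            )
    return np.array(placed)


def simulate_ms1_dataset(config: SimConfig) -> tuple[list[RunData], GroundTruth]:
    """Generate one MS1 run per sample plus the matching ground truth."""
    rng = np.random.default_rng(config.seed)
    n_scans = config.scans_per_run
    rt_lo, rt_hi = config.rt_range
    rt_grid = np.linspace(rt_lo, rt_hi, n_scans)
    dt = (rt_hi - rt_lo) / max(n_scans - 1, 1)
    sigma_rt = config.peak_sigma_scans * dt

    n_specific = config.n_groups * config.specific_features_per_group
    n_total = config.shared_features + n_specific

    # --- feature catalog (draw order: mz, rt, apex; shared then per group) ---
    if n_total:
        mzs = _place_mz(rng, n_total, config.mz_range, config.min_mz_spacing)
        margin = 4 * sigma_rt
        rts = rng.uniform(rt_lo + margin, rt_hi - margin, n_total)
        apexes = rng.uniform(*config.apex_intensity_range, size=n_total)
    else:
        mzs = rts = apexes = np.array([])
    catalog_rows = []
    idx = 0
    for _ in range(config.shared_features):
        catalog_rows.append(("shared", mzs[idx], rts[idx], apexes[idx]))
        idx += 1
    for g in range(config.n_groups):
        for _ in range(config.specific_features_per_group):
            catalog_rows.append((f"group{g + 1}", mzs[idx], rts[idx], apexes[idx]))
            idx += 1
    catalog = pd.DataFrame(catalog_rows, columns=["scope", "mz", "rt", "apex"])

    groups: dict[str, str] = {}
    runs: list[RunData] = []
    gt_rows = []
    for g in range(config.n_groups):
        group = f"group{g + 1}"
        for r in range(config.samples_per_group):
            sample_id = f"{group}_s{r + 1}"
            groups[sample_id] = group
            peaks_per_scan: list[list[tuple[float, float]]] = [
                [] for _ in range(n_scans)
            ]
            mask = (catalog["scope"] == "shared") | (catalog["scope"] == group)
            for _, feat in catalog[mask].iterrows():
                if rng.uniform() < config.dropout_prob:
                    continue
                apex = float(feat["apex"]) * float(rng.uniform(0.7, 1.3))
                lo_i = int(np.searchsorted(rt_grid, feat["rt"] - 4 * sigma_rt))
                hi_i = int(np.searchsorted(rt_grid, feat["rt"] + 4 * sigma_rt))
                sl = slice(max(lo_i, 0), min(hi_i + 1, n_scans))
                t = rt_grid[sl]
                profile = apex * np.exp(-((t - feat["rt"]) ** 2) / (2 * sigma_rt**2))
                noisy = profile + rng.normal(0.0, config.baseline_noise_sd, t.size)
                noisy = np.maximum(noisy, 0.0)
                mz_points = feat["mz"] + rng.normal(0.0, config.mz_jitter_sd, t.size)
                kept = noisy > 0
                if kept.sum() < 2:
                    continue
                for i, scan_i in enumerate(range(sl.start, sl.stop)):
                    if kept[i]:
                        peaks_per_scan[scan_i].append(
                            (float(mz_points[i]), float(noisy[i]))
                        )
                        if config.add_isotopes:
                            peaks_per_scan[scan_i].append(
                                (
                                    float(mz_points[i]) + _ISOTOPE_SPACING,
                                    float(noisy[i]) * 0.3,
                                )
                            )
                true_area = float(np.trapezoid(noisy[kept], t[kept]))
                gt_rows.append(
                    {
                        "group": group,
                        "sample": sample_id,
                        "scope": feat["scope"],
                        "mz": float(feat["mz"]),
                        "rt": float(feat["rt"]),
                        "true_area": true_area,
                    }
                )
            # baseline noise peaks, per scan
            for scan_i in range(n_scans):
                k = config.noise_peaks_per_scan
                if k:
                    noise_mz = rng.uniform(*config.mz_range, size=k)
                    noise_int = np.abs(
                        rng.normal(0.0, config.baseline_noise_sd, size=k)
                    )
                    peaks_per_scan[scan_i].extend(
                        (float(m), float(v)) for m, v in zip(noise_mz, noise_int)
                        if v > 0
                    )
            scans = []
            for scan_i in range(n_scans):
                pairs = sorted(peaks_per_scan[scan_i])
                merged: list[tuple[float, float]] = []
                for mz, inten in pairs:
                    if merged and mz - merged[-1][0] < 1e-9:
                        merged[-1] = (merged[-1][0], merged[-1][1] + inten)
                    else:
                        merged.append((mz, inten))
                scans.append(
                    Scan(
                        scan_index=scan_i,
                        ms_level=1,
                        rt=float(rt_grid[scan_i]),
                        mz_values=np.array([p[0] for p in merged]),
                        intensities=np.array([p[1] for p in merged]),
                    )
                )
            runs.append(RunData(sample_id=sample_id, rt_variant="minutes", scans=scans))

    features = pd.DataFrame(
        gt_rows, columns=["group", "sample", "scope", "mz", "rt", "true_area"]
    )
    return runs, GroundTruth(features=features, catalog=catalog, groups=groups)


def simulate_ms2_dataset(config: SimConfig) -> tuple[list[RunData], GroundTruth]:
    """Generate MS2 scans for a planted analog family plus decoys.

    Analog precursors carry every core fragment (the first one is the
    diagnostic ion) plus analog-specific side-chain fragments; decoy
    precursors carry only random fragments, none within 1 Da of the
    diagnostic. Precursors sit on distinct integer m/z values so unit-mass
    binning separates them.
    """
    if config.ms2_family is None:
        raise ValidationError("config.ms2_family must be set for an MS2 dataset")
    fam = config.ms2_family
    rng = np.random.default_rng(config.seed)
    diagnostic = fam.core_fragments[0] if fam.core_fragments else None

    lo, hi = fam.precursor_mz_range
    n_prec = fam.n_analogs + fam.n_decoy_precursors
    available = np.arange(int(np.ceil(lo)), int(np.floor(hi)))
    if n_prec > available.size:
        raise ValidationError("infeasible config: too many precursors for the m/z range")
    bases = rng.choice(available, size=n_prec, replace=False)

    def random_fragments(count: int, upper: float) -> list[float]:
        frags: list[float] = []
        while len(frags) < count:
            mz = float(rng.uniform(100.0, max(upper - 10.0, 110.0)))
            if diagnostic is not None and abs(mz - diagnostic) < 1.0:
                continue
            if any(abs(mz - f) < 1.0 for f in frags):
                continue
            frags.append(mz)
        return frags

    fam_rows = []
    scan_specs: list[tuple[float, list[float], list[float]]] = []
    for i in range(fam.n_analogs):
        precursor = float(bases[i]) + float(rng.uniform(-0.3, 0.3))
        side = random_fragments(fam.side_fragments_per_analog, precursor)
        frags = sorted(list(fam.core_fragments) + side)
        intens = [
            1000.0 if f in fam.core_fragments else 500.0 for f in frags
        ]
        scan_specs.append((precursor, frags, intens))
        fam_rows.append(
            {
                "kind": "analog",
                "precursor_mz": precursor,
                "precursor_bin": int(bases[i]),
                "fragments": ";".join(f"{f:.4f}" for f in frags),
            }
        )
    for i in range(fam.n_decoy_precursors):
        precursor = float(bases[fam.n_analogs + i]) + float(rng.uniform(-0.3, 0.3))
        frags = sorted(random_fragments(5, precursor))
        intens = [float(rng.uniform(200.0, 1000.0)) for _ in frags]
        scan_specs.append((precursor, frags, intens))
        fam_rows.append(
            {
                "kind": "decoy",
                "precursor_mz": precursor,
                "precursor_bin": int(bases[fam.n_analogs + i]),
                "fragments": ";".join(f"{f:.4f}" for f in frags),
            }
        )

    scans = []
    scan_i = 0
    for precursor, frags, intens in scan_specs:
        for _ in range(fam.replicates_per_precursor):
            jittered = [
                max(v * (1.0 + fam.intensity_jitter * float(rng.normal())), 1.0)
                for v in intens
            ]
            scans.append(
                Scan(
                    scan_index=scan_i,
                    ms_level=2,
                    rt=float(scan_i) * 0.01,
                    mz_values=np.array(frags),
                    intensities=np.array(jittered),
                    precursor_mz=precursor,
                    precursor_intensity=1e5,
                )
            )
            scan_i += 1
    run = RunData(sample_id="ms2_family_run", rt_variant="minutes", scans=scans)
    gt = GroundTruth(
        features=pd.DataFrame(
            columns=["group", "sample", "scope", "mz", "rt", "true_area"]
        ),
        catalog=pd.DataFrame(columns=["scope", "mz", "rt", "apex"]),
        groups={},
        ms2_families=pd.DataFrame(
            fam_rows, columns=["kind", "precursor_mz", "precursor_bin", "fragments"]
        ),
    )
    return [run], gt
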