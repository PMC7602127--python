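# Methods

This note documents the models and procedures implemented in `metabocomp`,
their assumptions, the parameters that matter, the numerical conventions,
and the limits of what the synthetic benchmark demonstrates.

## Scope and coordinate conventions

Input spectra are assumed **centroided**; profile-mode centroiding,
vendor raw formats, ion mobility, isotope-envelope deconvolution and
chromatogram alignment/warping are out of scope. m/z is in Thomson,
intensities are unitless, scans are 0-indexed in retention-time order, and
retention time is carried in a user-selected variant — minutes (default),
seconds, or the bare scan index. The scan-index variant exists because with
heterogeneous instruments and gradients an index-based rt can be the more
comparable axis; both are supported and the choice is the user's.

Missing bucket-table cells mean "feature not detected" and are imputed as
0. This matches the interpretation of absence used throughout: a feature
undetected in a sample contributes zero intensity to that sample's vector.

## MS¹ feature detection

The detector is a deterministic greedy scheme chosen so that outputs are
bit-stable and every rule is unit-testable:

1. **EIC tracing.** Scans are walked in rt order. Each centroid joins the
   open trace whose *running intensity-weighted mean m/z* lies within
   `mz_tol` (nearest centroid wins; exact ties go to the lower-m/z trace),
   otherwise it opens a new trace. A trace closes after `max_gap_scans`
   consecutive MS¹ scans without a member. Every centroid belongs to
   exactly one trace. Note a consequence of running-mean chaining: a mass
   drift faster than roughly `2·mz_tol` per few scans will split a trace,
   because the mean lags the drift.
2. **Peak picking.** Within a trace, local maxima (plateaus counted once)
   with apex intensity ≥ `min_height` become peak apices. Boundaries extend
   outward until intensity falls below `edge_frac × apex`, until the local
   minimum separating two apices (peaks are split at the minimum), or until
   the trace ends. Peaks spanning fewer than `min_scans` points are
   rejected. `min_scans` plays the role of the peak-*size* parameter;
   `edge_frac` and minimum-splitting are the peak-*shape* parameters.
3. **Integration.** The feature's integration value is the trapezoidal
   integral of intensity over rt across the peak's points (area, not
   height), its m/z the intensity-weighted mean of member centroids.

Defaults: `mz_tol` 0.01 Da, `rt_tol` 0.2 min, `min_scans` 3,
`max_gap_scans` 1, `edge_frac` 0.01, `min_height` 0 (instrument-dependent;
the benchmark uses 5·10³ against noise of sd 10³).

## Consolidation into a bucket table

Features from all samples are pooled and clustered greedily, highest area
first: the largest unassigned feature seeds a column and absorbs, from each
*other* sample, that sample's largest unassigned feature within `mz_tol`
and `rt_tol` of the seed. Each column therefore holds at most one feature
per sample — a bucket cell is one integration value. Column keys are the
area-weighted mean (m/z, rt) of the members, rendered `"mz@rt"`. Ties in
seed order break toward lower m/z, then lower rt. Greedy seeding by area
makes the decomposition deterministic and biases column centers toward the
strongest (best-measured) instances of a feature; chains of features each
within tolerance of the next but not of the seed split into separate
columns rather than smearing.

Row transformations offered: `raw`, `log10p1` (variance stabilization),
`tic` (row-sum normalization; all-zero rows stay zero), `presence_absence`.

## Sample comparison

Cosine distance is used because it is per-sample scale-invariant — total
loading and injection differences cancel — and bounded in [0, 1] for
non-negative data. Hierarchical clustering uses average linkage (UPGMA) by
default, the standard partner of cophenetic validation; single and
complete linkage are available. Dendrograms are exported as Newick with
ultrametric branch lengths (each node at half its merge height), so
leaf-to-leaf path lengths equal cophenetic distances. The cophenetic
correlation coefficient is the Pearson correlation between the condensed
original distances and the merge heights at which pairs first co-cluster;
it is undefined for n = 2 or when either vector is constant, and equals 1
exactly when the distances are ultrametric.

High-dimensional intensity vectors inflate absolute cosine distances (the
curse of dimensionality), so dendrogram *structure* and the cophenetic
coefficient carry the information; absolute merge heights should not be
over-interpreted.

## Univariate feature selection

Per feature, a Kruskal–Wallis rank test across groups (equivalent to the
Wilcoxon rank-sum for two groups) with Benjamini–Hochberg q-values over all
tested features. The rank test was chosen as the default because feature
intensities are zero-inflated and heavy-tailed; a one-way ANOVA F option
(`statistic="anova"`) exists for users who prefer a parametric test.
Constant features get statistic 0 and p = 1. A practical caveat documented
in the API: rank tests have a smallest attainable p-value fixed by the
group sizes (≈0.007 for 5 vs 5), so with few samples per group even a
perfectly separating feature cannot reach a small q-value after
multiplicity correction — a design consideration, not a software limit.
Prominence ranking uses the summed integration value across samples (or
within groups), ties toward lower m/z.

## Mass arithmetic and dereplication

Monoisotopic masses use the most-abundant-isotope table bundled in
`metabocomp.masses` (C = 12 exactly, H = 1.0078250319, N = 14.0030740,
O = 15.9949146, Na = 22.9897693, …). Adduct m/z is
(M + Δ − z·mₑ)/|z| for positive ions with `electron_correction=True`
(mₑ = 0.000549 Da); the correction is an explicit flag because published
values mix conventions — sodiated-ion calculations typically include it,
while "ion formula" sums (e.g. C9H19O2 for an [M+H]+ ion) do not.
RDBE = C + 1 + (N − H − halogens)/2, computed for the standalone neutral
formula; embedded-substructure bookkeeping (where a fragment's effective
unsaturation differs by its attachment bonds) is deliberately not
attempted. Reference matching emits an annotation for every
(feature, compound, adduct) pair within `mz_tol` (Da by default — suited to
unit-resolution data; convert externally for ppm work) and flags everything
else "not dereplicated". Fragment matching allows hydrogen-rearrangement
shifts of up to `max_h_shifts` hydrogen masses, reporting the smallest
shift.

## MS² analog-family pipeline

MS² scans are binned by precursor m/z rounded **half-up** to
`bin_decimals` decimal places (0 → unit-mass bins, appropriate for
ion-trap data; the parameter corresponds to the order-of-magnitude knob of
comparable pipelines and is documented here as an interpretation). Bins
survive only if at least one member scan has a peak within `fragment_tol`
(default 0.5 Da) of the diagnostic fragment. Within each retained bin,
scans are vectorized on a fixed m/z grid of `fragment_bin_width` (default
1.0 Da, anchored at 0), compared by cosine distance, clustered by average
linkage, and the tree is cut at `cluster_cutoff` (default 0.15) —
separating isomers and chimeric scans that share a precursor bin. Each
cluster becomes a consensus spectrum: fragment bins present in ≥
`consensus_min_fraction` (default 0.5) of member scans are kept, with
intensity-weighted mean m/z and the mean of per-scan relative intensities,
renormalized to base peak 1. The 0.5 fraction and weighted-mean rule were
chosen for robustness to single noisy scans; the whole pipeline is a pure
function of its inputs.

## Synthetic benchmark

The generator emulates a multi-region field study: `n_groups` = 5 regions ×
3 samples, 30 shared + 10 region-specific features per region, uniformly
placed in m/z 150–900 (minimum spacing 0.05 Da; denser configurations are
rejected as unresolvable) and rt 0–12 min, Gaussian elution with σ = 3 scan
intervals on a 200-scan grid, apex intensities uniform in 1e5–1e6 over
additive baseline noise of sd 1e3 (signal-to-baseline ≥ 100), per-sample
apex jitter ±30%, 5% feature dropout, 8 random noise peaks per scan, and
m/z jitter of sd 0.001 Da per point. The MS² dataset plants a 5-analog
family (core fragments at m/z 168.10 and 110.07 plus analog-specific side
fragments) among 20 decoy precursors lacking the diagnostic ion, 4
replicate scans each with 10% intensity jitter, on distinct integer
precursor masses. A single seeded generator drives all draws in a fixed
order (feature placement, then samples in group order, then per-scan
noise), so a fixed seed reproduces output files byte-for-byte; recorded
ground-truth areas are the trapezoidal integrals of the actually emitted
(noise-included) points.

What passing the benchmark shows: the detector recovers well-separated
Gaussian peaks at high signal-to-baseline (recall ≥ 0.95, precision ≥
0.90), clustering recovers planted group structure, the MS² filter
retrieves exactly the planted family, and feature selection finds planted
drivers while controlling the false-discovery rate on pure nulls. What it
does **not** show: performance on tailing/fronting peaks, co-eluting
isobars, mass-calibration drift, isotope envelopes and adduct clusters
(an `add_isotopes` stress flag exists), matrix effects, or real
between-batch variation. Published coefficients from real field studies
(e.g. dendrogram cophenetic correlations near 0.9) depend on those raw
data and are not re-derivable from simulation; the benchmark instead
validates each computation against independent oracles (hand-computed
closed forms, brute-force re-implementations) and planted ground truth.

## Numerical and degenerate-case choices

* All tie-breaks are specified and deterministic (lower m/z, then lower
  rt; smallest leaf index in linkage) so repeated runs are byte-identical.
* mzXML is written with uncompressed network-order 64-bit peak encoding;
  round-trips through the reader preserve rt and peaks to < 1e-6.
* Empty inputs: a run with zero scans at the requested MS level is an
  error; an empty feature pool consolidates to an empty table (warning
  case, not an error); a singleton precursor bin yields one singleton
  cluster; `tic` on an all-zero row leaves it zero.
* Exit codes of the CLI: 0 success, 1 usage/validation error, 2 data
  error; every command writes a manifest (inputs, resolved config + hash,
  version) for provenance.

## Problem sizes used in the test-suite

The bundled benchmark runs 15 samples × 200 scans for the MS¹ path, a
25-precursor × 4-replicate MS² dataset, 100 randomized trials per oracle
equivalence, and 200 pure-null replicates of 20 × 200 tables for the
false-positive-rate check — sizes chosen so the full validation runs on a
laptop in well under a minute per component while keeping the statistical
checks meaningful.
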