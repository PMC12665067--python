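# Methods

## The data model

A DNB capture array records, per spot `(x, y)`, the number of molecular
identifiers (MIDs) captured per gene — the GEM table.  Capture is
sparse (on the order of one molecule per capturing spot), so all
analysis operates on square bins of `bin_size × bin_size` DNBs
(default Bin50): bin indices are `floor(coord / N)`, bins are half-open
`[kN, (k+1)N)`, and binning conserves total counts exactly.  Per-bin
capture averages are reported over occupied bins by default; because
the appropriate denominator (occupied bins, bins under the tissue, or
the whole grid) is a genuine convention choice, it is exposed as an
option rather than fixed.

## Synthetic seed sections

The simulator emulates a lateral-plane section of a 14 DPA wheat seed
on an abstract DNB grid (the physical pitch in µm is irrelevant to the
analysis and is not modelled):

* **Geometry.** Seven concentric elliptical bands (outermost to
  innermost: pericarp, sub-aleurone, central endosperm, inner
  endosperm, transfer cells, outer crease, inner crease) partition an
  ellipse with semi-axes `0.49·scale × 0.46·scale`; the embryo is a
  disc centred at 0.62 of the major semi-axis, overriding the endosperm
  bands it overlaps.  Annuli are inner-inclusive, outer-exclusive, so
  the partition is unambiguous.  Radial band edges
  (0, .22, .37, .51, .64, .77, .89, 1) make every band roughly two
  Bin50 bins thick at the default `scale = 1500`.
* **Boundary quantization.** By default the zone membership of a DNB is
  decided at the centre of its 50×50 lattice cell, so zone boundaries
  follow the Bin50 lattice and every analysis bin has a single true
  zone.  With smooth boundaries (`quantize=1`) most bins at this grid
  size straddle two bands, and those mixture bins form their own
  gradient communities under any clustering of expression — a
  consequence of compressing eight zones into a ~30-bin-diameter
  section, not a property of the method.  Quantization keeps the
  planted zones resolvable at the scale analysed; real chips are one to
  two orders of magnitude larger, where partial-bin mixing affects only
  a thin boundary fraction.
* **Expression.**  Each zone has a Poisson program per gene: 40
  housekeeping genes at a common baseline (0.05 transcripts/DNB), five
  planted markers per zone whose in-zone rate (0.7) exceeds their rate
  everywhere else by the configurable marker fold (default 10×), and
  three homeolog triads whose relative A:B:D rates follow the overall
  MID totals observed for puroindoline-B (2836 : 7387 : 24634,
  endosperm zones), a metallothionein isoform with no A homeolog
  (2131 : 21397, embryo/pericarp/crease) and α-amylase/subtilisin
  inhibitor (123 : 4286 : 2730, pericarp).  Outside the tissue a weak
  background program (0.05 transcripts/DNB total) emulates ambient
  noise.  An optional `side_asymmetry` factor multiplies one lateral
  half of the section, mimicking the brighter side of a real section;
  it defaults to 1 (off).
* **Capture.**  Counts are independent Poisson per (DNB, gene) with
  rate `zone_rate × capture_rate`; spots with zero total are omitted,
  like non-capturing DNBs.  `calibrate_capture_rate` solves
  `E[MIDs per capturing DNB] = Σλ / Σ(1−e^{−λ}) = 1.3` by bisection
  (the per-DNB statistic of the real focus chip), giving ≈ 0.065 under
  the default model.  Overdispersion (negative binomial) is deliberately
  not modelled.
* **Fold artifact.**  An optional duplicated-tissue patch outside the
  section boundary carries the central-endosperm program at twice the
  density (a folded-over flap captures two tissue layers); it exists to
  exercise the cluster-discard rule.

What the simulator does *not* emulate: cell-scale texture, transcript
diffusion between neighbouring spots, segment-specific capture
efficiency, overdispersed counts, or imaging-based tissue masks.
Passing recovery tests therefore demonstrates correctness of the
pipeline's bookkeeping and statistics under a clean generative model,
not robustness to every artefact of real chips.

## Clustering

Bins with fewer than 30 total MIDs are removed (boundary inclusive) —
on the default synthetic section this deletes essentially all
background bins, whose expected total is ~10 MIDs.  Counts are
log1p-transformed (natural log, zeros preserved) with no prior
depth scaling (a library-size option exists but defaults off), then
embedded with exact-solver PCA; component signs are fixed by forcing
each component's largest-magnitude loading positive, making the
embedding fully deterministic.  `n_components` defaults to 50, clamped
to the data size.

The expression graph links each bin to its k = 15 Euclidean nearest
neighbours in PCA space (union-symmetrised, weight `1/(1+distance)`).
The spatial graph links bins within Chebyshev distance 1
(8-neighborhood).  Each spatial edge carries the mean expression edge
weight — with unit spatial weights the blend is dominated by the
spatial graph at any λ, and ring-shaped zones shatter into arcs; the
rescaling makes λ an interpretable balance, with λ = 0.5 by default.
Leiden (RB-configuration modularity, resolution 1.0) runs on the
blended graph after bins are put in canonical (bin_x, bin_y) order, so
labels are invariant to input order; labels are renumbered by
decreasing cluster size.

Cluster retention: with a tissue mask (from the synthetic ground truth
or a user-supplied bin list), a cluster is discarded when more than
half its bins fall outside; without a mask, when its median bin total
falls below the 10th percentile of all bins.  The cluster count is
emergent — eight is the outcome on the default section, not a forced
parameter.

## Marker ranking

Welch's unequal-variance t statistic per gene, cluster vs all other
retained bins, on raw MID counts (not log1p): raw counts are what the
test prescribes, and the unequal-variance form is robust to the strong
depth differences between zones.  Genes with zero variance in both
groups get t = 0.  Ranking is by descending t with ties broken by
higher in-cluster mean then gene id; the default report keeps the top
5 per cluster.  Across replicates, clusters are matched by tissue
annotation (never by raw label) and a consensus table counts how many
replicates nominated each (tissue, gene) pair.  Ranks, not p-values,
are the output, so no multiplicity correction applies here.

## Permutation testing of expression differences

Spatial counts are highly zero-inflated, so group differences are
tested with a permutation test rather than a t- or rank-based test.
The statistic is the absolute difference of per-bin means of raw
counts — the minimal two-sided choice for "is expression different".
`M` uniformly random reassignments of the pooled values into groups of
the original sizes are drawn (default M = 500,000); internally the
pooled values are sorted and the smaller group's sum is the working
statistic, which makes `test(x, y)` and `test(y, x)` byte-identical for
the same seed.  Integer counts are compared exactly (sums below 2⁵³).

With `b` permuted statistics ≥ the observed one:

* `p̂ = (b+1)/(M+1)` — the add-one estimate, never zero;
* `ci_upper` — the upper limit of the two-sided 99.9% Clopper–Pearson
  interval for the exceedance probability (`b = 0` reduces to
  `1 − (α/2)^{1/M}` ≈ 1.52·10⁻⁵ at M = 500,000);
* `p_adj = min(1, ci_upper · K)` — Bonferroni over the K tests of the
  run.  K defaults to the number of tests actually executed and can be
  overridden to reproduce a fixed correction factor; the decision value
  is deliberately the adjusted *bound*, i.e. a value the true adjusted
  p is below with high confidence.

An exact-enumeration twin (`exact_permutation_test`, bounded at
C(n₁+n₂, n₁) ≤ 10⁶) serves as the oracle in tests.

Inputs come from a stratified subsample: `max(floor(0.05·n), 20)` bins
per tissue group, without replacement, deterministic per seed.  The
floor of 20 keeps tests non-degenerate on desk-scale sections.  Tissue
contrasts default to the four macro groups (endosperm, pericarp,
crease, embryo); the eight fine zones can be used instead.  Homeolog
pairs are tested unpaired on the pooled sampled bins.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeds
  recorded in the run manifest; identical configs give byte-identical
  artifacts for deterministic stages.
* Permutation exceedance comparisons use a 10⁻⁹ relative tolerance so
  float round-off cannot drop tied permutations.
* Degenerate inputs are defined, not errors: all-identical pooled
  values give T = 0, b = M, p̂ = 1; an empty filter result raises with
  advice; clusters with fewer than two bins are skipped with a warning.
* Test problem sizes: the null-calibration study (500 contrasts) runs
  at M = 2,000 permutations with subsample-scale vectors, and the
  recovery/power studies use the default 1500-DNB section; these sizes
  are the package's chosen desk-scale study conditions.

## Known limitations

* Poisson capture without overdispersion overstates the power of the
  permutation test relative to biological replicates.
* The lattice-quantized zone template removes partial-bin mixing, so
  zone-recovery scores here are upper bounds on what smooth tissue
  boundaries would give at this section size.
* The 2–3-fold planted homeolog ratios (e.g. puroindoline-B A vs B)
  are genuinely under-powered at the 5%/20-bin subsample size and are
  reported as non-significant; only the strong (≥ 8.7-fold) biases are
  expected to be called.
* Cross-chip batch correction, highly-variable-gene selection and
  image-based masks are out of scope.
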