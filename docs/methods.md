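# Methods

This note documents the models and procedures implemented in tumorkit,
the conventions and defaults that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the design was genuinely open.

## ctDNA panel and detection (`tumorkit.ctdna`)

**Panel design.** Candidate SNVs are eligible for bait design when the
tumor VAF exceeds 5 %, the matched-normal VAF is below 2 %, tumor depth
exceeds 30× and normal depth 15× (all strict inequalities; a value
exactly at a threshold fails). The monitored panel then drops baits with
a QC flag (e.g. inconsistent capture coverage) and any site whose VAF in
pooled negative-control cell-free DNA exceeds 1 %.

**UMI consensus.** A family is all reads sharing a (UMI, site-window)
pair. Families with fewer than 3 reads are discarded. Per position the
modal base is emitted when its fraction of non-N reads is ≥ 0.9
(boundary inclusive — 9/10 agreement passes); otherwise N. N inputs are
excluded from both numerator and denominator of the agreement fraction
and of downstream VAF tallies: an N carries no evidence, so it neither
supports nor contradicts. Three bases at each end of every consensus are
masked to N (fragment-end artifacts); consensus reads with no interior
left are dropped with a warning. Overlapping mate pairs merge into a
single read so one molecule is never counted twice: agreeing overlap
bases pass through, disagreements become N (conservative, in keeping
with the duplex error-suppression intent), and N against a real base
yields the base.

**Beta-overlap detection.** Counts (k, n) are modeled with a flat
Beta(1, 1) prior, giving the posterior Beta(k+1, n−k+1) on the true VAF.
The detection statistic is the Weitzman overlapping coefficient
∫ min(f₁, f₀) between the sample and negative-control posteriors. The
flat prior is a choice — the plug-in sampling-distribution variant gives
indistinguishable answers at panel depths (10³–10⁵) but is undefined at
k = 0, which background sites routinely are.

*Numerics.* The log-density difference of two Beta densities is
a·log x + b·log(1−x) + c, monotone or unimodal on (0, 1), so the
densities cross at most twice. The crossings are bracketed on a grid of
both posteriors' quantiles and refined by Brent's method; each resulting
piece is integrated exactly through the regularized incomplete beta
function. Agreement with an independent fine-grid Riemann oracle is
~10⁻⁸, far inside the 5×10⁻³ the tests require. The statistic is exactly
1 for identical counts, symmetric in its arguments, and decays
monotonically with VAF separation at fixed depths.

Detection is declared at p ≤ 0.05 (the boundary counts as detected; the
convention only states that p > 0.05 is non-detection). Group-level
tests pool k and n across the member sites of a mutational group before
computing the statistic — pooling weights deeper sites more, which is
the behavior wanted when groups mix depths; combining per-site p-values
instead would discard that information.

## Variant classification and phylogeny (`tumorkit.evolution`)

Observations below 5 % VAF or 30 reads of depth are filtered; values
exactly at a boundary are kept ("lower than" removes, so ≥ stays).

Per (variant, sample) the evidence state is **called** (caller flag),
**supported** (not called but ≥ 2 supporting reads), or **absent**. The
ubiquitous / shared / private category counts called evidence only by
default — the supported state is an annotation of borderline evidence,
not presence. A flag (`include_supported`) switches to counting
supported evidence as presence, since whether borderline re-detection
should count is a judgment call; both modes are tested. Variants called
in no sample are excluded with a warning. The binary matrix marks 1 only
for called evidence; an all-zero outgroup row can be appended to
represent the germline state.

Genetic distance is the pairwise mismatch count between binary rows.
The minimum-evolution tree enumerates **all** unrooted binary topologies
(3–8 taxa; 10 395 topologies at 8), fits branch lengths by OLS of path
lengths against the observed distances, clamps negative estimates to
zero for the total-length criterion (raw values retained in
`raw_lengths`), and selects the minimum-total-length topology. For the
5–7 leaves of a per-patient study this regime is exact and serves as its
own optimality oracle; beyond 8 taxa the function refuses and points to
heuristic ME software. Ties break on the canonical label-sorted topology
string, so results are deterministic. On additive (tree-realizable)
matrices the fit is exact: topology recovery is 100/100 on seeded
5-taxon fixtures with fitted-distance error < 10⁻⁹.

Newick serialization orders children canonically and round-trips through
standard parsers (verified against dendropy patristic distances).

## Regulator activity (`tumorkit.regulon`)

The network is a SIF table restricted to `controls-expression-of` edges
whose regulator and target are both measured. Signs default to +1 with a
warning when absent. Two-step (secondary) interactions can be folded
into direct edges with the sign product via `expand_secondary`; this is
opt-in, and composites with ambiguous sign are dropped.

**Edge weights.** w = ρ·(1−p_F), with ρ the Spearman correlation of
regulator and target across samples and p_F the p-value of the
regression F-test (F = t² of the slope). The form is sign-preserving and
monotone in both evidence sources; it is one defensible combination of
rank-order and linear-dependency evidence, exposed as a plain column so
alternatives can be substituted. Undefined statistics (constant vectors)
give weight 0. At least 4 samples are required.

**Signature.** score_g = expr_g(sample) − median over the cohort,
rank-sorted descending. The cohort median stands in for the inactive
baseline; the signature is only meaningful when most cohort samples do
not share the queried activity state.

**Components.** All use a robust quantile transform: scores are
winsorized at median ± 3 scaled MADs, ranked ascending with ties
averaged, and mapped to rank/(m+1) ∈ (0, 1). "Directional" means a
negative edge reads the reversed ranking (a repressed target supports
activity by being lowly expressed).

- *Local delta concordance*: within a regulon, Spearman correlation of
  |w| with the directional target rank, computed separately for
  positive- and negative-edge groups (≥ 2 informative edges each) and
  averaged over the groups that exist — so a regulon dominated by one
  sign still contributes.
- *Local enrichment*: directional quantiles of the regulon's targets
  within the **network-covered** feature space (all genes that are
  targets of any weighted edge), summarized by the |w|-weighted median;
  the weighted median realizes "repeat each quantile proportionally to
  its weight" in the continuous limit and reduces to the ordinary
  median at equal weights. The local space is network-wide rather than
  per-regulon: a per-regulon ranking is expression-invariant for a
  sign-consistent regulon (its internal positions are always 1..m), so
  it could not register enrichment at all.
- *Global enrichment*: the same construction over **all** genes in the
  signature, unweighted median.

Each component is reported as (median − 0.5) × 2 ∈ [−1, 1], so the
no-activity expectation is 0; permutation checks over 200 null seeds
hold every component's mean within ±0.05. Components are undefined (and
skipped) when a regulon has no target in the signature.

**Integration.** Each component is standardized across regulators by its
median and normal-consistent MAD (zero MAD ⇒ zeros) and the integrated
score is the mean of available standardized components; regulators are
ranked by it. `activity_delta` reports both difference and ratio of
integrated scores between two timepoints, because the "fold-change in
activity" one wants to quote is sometimes the one and sometimes the
other.

## Closed-form scores (`tumorkit.scores`)

- Pathway score: (Σ positive predictors − Σ negative predictors) / n
  predictors used; predictors missing from a sample are excluded with a
  warning and the denominator shrinks.
- Cohort z-score: (x − cohort median)/cohort SD per protein
  (sample SD, ddof = 1); zero-SD rows get z = 0, flagged.
- PAM50: the query sample joins the background cohort (e.g. 20 ER+ and
  20 ER− tumors), the combined matrix is mean-centered per gene, and the
  centered query is Spearman-correlated with each subtype centroid over
  the shared genes (≥ 10 required); highest correlation wins, exact ties
  resolve in the fixed order LumA, LumB, Her2, Basal, Normal, and a
  negative best correlation is flagged rather than suppressed. The
  assignment is exactly invariant under positive affine transforms of
  the expression scale; for general monotone transforms it is only
  approximately invariant, because mean-centering precedes the rank
  statistic.
- TMB: nonsynonymous mutation count / targeted megabases. Counting and
  effect annotation are inputs.
- Neoepitopes: retained when the minimum binding affinity across patient
  alleles is strictly below 500 nM; shared neoepitopes are the presence
  intersection across a sample set. Both are idempotent set operations.

## Spatial statistics (`tumorkit.spatial`)

Marker intensities divide by their per-image maximum (range 0–1).
Gating trees are explicit user configuration — thresholds on normalized
intensities, the ≥ branch taking boundary values — because the source
workflow gates manually; no auto-thresholding is attempted. Population
counts propagate down the tree (parent = sum of children exactly), and
composition reports percent of total nucleated cells, percent of parent
(missing when the parent is empty), and cells/mm². Cells and areas from
multiple ROIs must be pooled before percentages are formed.

Distance to the ECM mask is Euclidean from the cell centroid to the
nearest positive **pixel center**, with cells whose containing pixel is
positive assigned distance 0; sub-pixel mask geometry is ignored, which
bounds the error by pixel_size/√2. The implementation (k-d tree over
positive pixel centers) matches an exhaustive all-pixel scan exactly.

Bins are half-open — [0, 25), [25, 50), [50, 75) µm, a distance of
exactly 25 µm falling in the second bin — and cells beyond 75 µm are
excluded. One-way ANOVA compares intensity across bins with ≥ 2 cells;
fewer than two usable bins marks the result untestable rather than
significant. The Bonferroni family is all marker × sample tests in one
invocation (the family is a per-run choice, exposed as `n_tests`), the
adjusted p is capped at 1, and significance requires adjusted p < 0.001.
Under a null (zero-slope) fixture the unadjusted rejection rate at
α = 0.05 sits in [0.03, 0.07] over 1000 seeds.

## Synthetic data (`tumorkit.simulate`)

All generators draw from `numpy` Generators seeded by
(`SimParams.seed`, stream), one independent stream per generator, so
identical parameters give bit-identical outputs and no global state
leaks between stages.

- **Clonal biopsies.** A clone carries every mutation on its root path.
  Per biopsy and variant: depth ~ Poisson(depth_mean), supporting reads
  ~ Binomial(depth, purity × 0.5 × presence) — heterozygous and
  copy-number neutral, keeping the true VAF analytic. The caller
  emulation flags a variant called at ≥ 3 supporting reads and
  VAF ≥ 5 %, mirroring the downstream filter; it is a fixture
  convention, configurable at the call sites that consume it. The
  bundled `example_tree` has five biopsies (PT, Bx1–Bx4), 200 mutations
  over truncal/shared/private branches, purity 0.6. At depth 10⁵ the
  classification recovers the branch truth exactly; mean VAF of carried
  variants converges to purity × 0.5 within 3 SE.
- **UMI families.** Family sizes are geometric with mean 5 by default
  (or constant); each family draws a true allele (mutant with
  probability true_vaf) over a 9-base window and corrupts each read base
  to a uniformly random other base with probability error_rate. Indels,
  quality strings, and FASTQ emission are deliberately not modeled — the
  consensus logic under test is substitution-driven.
- **Regulator expression.** Genes are the union of regulators and
  targets; baseline is iid N(0, noise_sd²). Active regulators raise
  their own expression and shift each target by sign × effect_size in
  the designated active samples. The active set is the last ⌈n/6⌉
  samples: the median-reference signature presumes the cohort median
  represents the inactive baseline, so the planted condition must be a
  minority — emulating a patient's few samples against a background
  cohort. Defaults: 30 samples, noise_sd 1, effect 3 × noise_sd. The
  planted regulator (50 regulators × 20 disjoint targets) is recovered
  as top-ranked in ≥ 95/100 seeds.
- **Spatial tissue.** A circular tumor nest (radius 100 µm) inside an
  annular collagen rim (width 10 µm) rendered at 1 µm/pixel; cells
  uniform over the nest; intensity = 500 − slope × (distance to rim) +
  N(0, 50²), clipped at 0. The generator's analytic rim distance is
  independent of the mask-based measurement under test. Clipping at 0
  slightly truncates the far-bin noise at steep slopes; at the default
  settings the truncated mass is negligible.
- **Additive distances.** Random unrooted binary topologies grown by
  uniform edge attachment, branch lengths U(0.1, 1); leaf path lengths
  give exactly tree-realizable matrices with known splits, the oracle
  for minimum-evolution recovery.

What passing these tests does **not** show about real data: no
copy-number variation, tumor-in-normal contamination, or subclonal
mixtures within a biopsy; no sequence-context-dependent error profiles;
regulons with disjoint targets and homoscedastic expression noise; a
single convex nest geometry with an ideal mask. The fixtures validate
the statistical machinery, not the biology of any particular dataset.

## Problem sizes and runtime

The test-suite simulation studies use: 100 seeds for minimum-evolution
and regulon recovery and for the spatial gradient study, 200 seeds for
regulon null calibration (20 regulators × 10 targets, n = 20), 1000
seeds for spatial type-I control (300 cells per seed), 5000 UMI families
for error suppression, and 100 random count pairs against a 4×10⁵-point
grid oracle for the overlap statistic. These sizes put binomial
uncertainty well inside the tested margins while keeping the whole suite
under two minutes on one CPU; `scripts/acceptance.py` recomputes the
same quantities at the same sizes.

## Known limitations

- The exhaustive minimum-evolution search is exact but exponential;
  it stops at 8 taxa by design.
- The beta-overlap statistic is a calibrated overlap coefficient, not a
  frequentist p-value; its null distribution is not uniform.
- The three regulon components and their combiner are concrete
  renderings of a prose description; they are permutation-calibrated and
  exposed behind small functions precisely so alternatives can be
  swapped in.
- `pam50_assign` requires the caller to supply the background cohort and
  centroid table; no reference data ships with the package.
- Distance-to-ECM ignores sub-pixel geometry and measures to pixel
  centers (error ≤ pixel_size/√2).
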