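# Methods

`sedadrivers` links a century-scale, sediment-core eDNA community time
series to yearly climate and biocide-sales records. The pipeline has
five inferential stages — phase-level diversity shifts, sparse-CCA
driver ranking, sliding-window permutation correlation with a triple
filter, joint biocide x climate effect detection, and bookkeeping
summaries — plus a synthetic-core generator that defines the study
conditions every stage is evaluated under. This note records the
models, the parameters that matter, the numerical choices, and the
limits of what the synthetic evaluation shows.

## Data model and time alignment

A core is an ordered set of dated layers; each layer carries a
half-open calendar span `[mid − δ_left/2, mid + δ_right/2)` built from
the gaps to neighbouring midpoints, so spans tile the record without
double-counting years. A driver's value on a layer is the unweighted
mean (optionally the sum, for sales quantities) of its yearly values
inside the span; a layer missing any covered year is **excluded** for
that driver, never imputed. Because biocide sales begin in 1960, each
biocide's analysis axis is the ~18 most recent layers, while climate
axes span all ~33 datable layers. Drivers left with fewer than 5
layers (the minimum window) are flagged unanalyzable.

## Diversity stages

Alpha diversity is Shannon entropy in bits, compared across lake
phases with a Kruskal-Wallis test. Beta diversity uses Bray-Curtis
dissimilarity by default — any symmetric distance matrix (e.g. a
weighted-UniFrac matrix from a tree-aware pipeline) can be supplied —
and pairwise PERMANOVA between phases: pseudo-F from the standard
Gower-centering algebra, R² = SS_between/SS_total, permutation
p-values that include the observed statistic
(`p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1)`, 999 permutations by
default), and Benjamini-Hochberg adjustment across the pairs of one
analysis. An exhaustive label-enumeration mode exists for small n and
anchors the Monte-Carlo p in tests.

## Sparse CCA driver ranking

With X (layers x families, z-scored relative abundances) and Z
(layers x drivers, z-scored), components are extracted by penalized
rank-one decomposition of M = XᵀZ: alternating soft-thresholded
updates of u and v under unit L2 norms and L1 budgets `c·√p`, the
threshold located by bisection, deterministic initialization from the
dense leading singular vector, rank-one deflation between components.
With `c = 1` the procedure reduces to the SVD (tested to 1e-8).
Defaults: K = 5 components, `c_u = 0.5`, `c_v = 0.7`. Driver
importance is `Σ_k d_k · |v_k[driver]|`, ranked within the climate and
biocide classes separately (ties alphabetical); "variance explained"
per class is a redundancy index — the fraction of X's centered
variance captured by regressing its columns on the K canonical
variates of a class-restricted refit.

At the emulated scale (17 common layers, 20 families) the ranking is
descriptive, not inferential: the leading singular structure of M is
substantially noise-driven, and ranking order varies between seeds.
For this reason no downstream stage gates on the ranking.

## Sliding-window correlation and the triple filter

All contiguous windows of at least 5 time points (15% of a 34-layer
record) are enumerated; windows with more than 50% zeros on either
side (strict majority) or a constant series are discarded.

Two measured failure modes shaped the inference design:

1. **Winner's curse.** Testing only the selected best window against
   its own within-window permutation null passes essentially every
   family under a global null — the max over ~100-500 overlapping
   windows is far into each single window's tail.
2. **Powerless raw statistic.** The plain max-|r| scan statistic
   cannot separate signal from noise: 5-point windows reach |r| ≈ 0.95
   under null and alternative alike.

The scan therefore compares windows on a length-adjusted evidence
scale. For each window length w the admissible max |r| is converted to
a per-window p (two-sided t tail, floored at the exhaustive
permutation minimum 2/w! for w ≤ 10), and the scan statistic is

    max_w [ −log p_w − log n_w + (w − T)·log 2 ],

a weighted-Bonferroni min-p with a geometric prior favouring sustained
windows (the prior masses sum to ≤ 2). The family-level p-value
permutes the driver series as a whole and recomputes this statistic on
each permutation (vectorized with prefix sums), so it is exact under
the exchangeable null by construction; `B = 10,000` permutations by
default, smaller B in tests. The reported best window is the argmax of
the same evidence score (ties: longer window, then earlier start);
max-|r| selection remains available as an alternative criterion.

Scan p-values are BH-adjusted across all family x driver tests within
a driver class (climate and biocides separately). A link passes only
the triple filter: best-window |r| > 0.5, adjusted p < 0.05, and
within-family recall > 0.5 — the fraction of the family's member ASVs
that individually satisfy the same |r| and (within-family BH-adjusted)
fixed-window permutation-p criteria in the family's best window. The
empirical 90% quantile of recall rates is reported alongside the calls
but is not used as the gate. The test is two-sided throughout; the
sign of the best-window r is recorded with each call.

## Joint biocide x climate effects

The joint stage must not inherit the individual scans' selected
windows (that re-imports the winner's curse; an early version calling
joint effects on windows assembled from the two individual best
windows produced essentially arbitrary calls). Instead, for each
family and (biocide, climate) pair:

1. the **shared axis** is the fixed set of layers valid for both
   drivers;
2. the combined series is the equal-weight average of the two z-scored
   drivers, `J = (z_bio + z_cli)/2`;
3. the candidate window is the best evidence window of the family
   against J;
4. *combined significance* requires both drivers individually
   significant on that one fixed window (permutation p < 0.05 each)
   with mean(|r_bio|, |r_cli|) > 0.5;
5. *joint effect* requires the scan-level permutation p of the family
   against J (permuting J as a whole equals shuffling the paired
   (bio, cli) rows jointly), BH-adjusted across the joint batch, below
   0.05, **and** `|r_joint| > max(|r_bio|, |r_cli|)` strictly on the
   candidate window.

The equal-weight combination — not a least-squares fit — keeps the
strict-improvement criterion falsifiable: a fitted multiple
correlation can never be smaller than either individual correlation,
while the fixed combination can. A family loading on only one driver
cannot satisfy the strict inequality (Pearson r with any combination
that includes the family's exact driver cannot exceed 1).

Chemical-level ranking within a biocide type discards chemicals with
more than 50% absent values over the analysis range or best |r| < 0.5,
and ranks survivors by |r| descending (ties alphabetical). The joint
frequency matrix counts distinct families with a joint effect per
(biocide type, climate variable) cell, optionally split by domain
grouping (eukaryote/prokaryote).

## Enrichment and summaries

Pathway enrichment consumes a user-supplied differential term list
(differential-abundance calling is upstream of this package): per
pathway a 2x2 table against the background, a two-sided Fisher exact
test (verified against hypergeometric tail summation), odds ratio
(a·d)/(b·c) with explicit infinity when a cross cell is zero. Link
summaries count passing families per driver, with percentages of the
class total rounded half-up at the table's printed precision (integer
for small tables, one decimal for large ones) and positive/negative
sign splits; percentages always recompute from the stored counts.

## The synthetic generator

The generator emulates the target system's data shape: 34 layers of
0.5 cm spanning 1916-2016 (~3 years per layer), phases SP < 1958,
E 1958-1979, P 1980-1998, R ≥ 1999; climate = linear trend + AR(1)
noise over the full range; biocide sales absent before 1960, then a
smooth unimodal pulse peaking in the pesticide era with heavy yearly
noise (sd 0.6 x amplitude — sales records swing with regulation and
prices, and layer aggregation averages yearly noise by ~√3; distinct
peak years/widths per type keep the four types distinguishable).
Family latent log-abundance is

    λ_f(t) = baseline_f + phase_offset_f(t) + Σ β·z_driver(t) + AR(1) noise,

with phi = 0.35 at layer resolution (yearly persistence ~0.7 over
3-year layers) and innovation sd 0.4. Counts are a multinomial split
of softmax(λ) across each family's ASVs (within-family Dirichlet
shares drawn once) conditioned on a log-normal library size per layer
(median 10,000 reads) — preserving the compositionality that
rarefaction assumes. About 10% of ASVs deliberately lack a family rank
and fall back to order-level labels, exercising the
lowest-available-rank rule; these are drawn only from families without
planted structure so the ground truth stays well defined.

β is initialized from the variance identity `r* = β/√(β² + σ²)` on the
standardized driver (σ = stationary AR sd) and refined by two
deterministic secant steps on the realized pre-sampling
relative-abundance correlation, keeping the best-tried value. The
refinement matters because the exponential count link caps the
attainable Pearson correlation of a *relative abundance* with a driver
near ~0.75 for r* = 0.8 — pushing β further adds convexity as fast as
signal. Realized correlations therefore center at ~0.70-0.78, inside
the generator's documented ±0.15 calibration band.

Joint families load on the equal-weight standardized driver sum with a
combined target correlation of 0.9 and adverse sign on both drivers
(equal signs are a *requirement* for the equal-weight joint criterion
to be satisfiable). Phase-shift families get an E-phase offset (±1.2
in log abundance): any regime shift is structurally collinear with
era-structured drivers (a semi-pristine step correlates ~0.7 with a
century warming trend; an eutrophic-era box ~0.9 with an early-peaked
pulse), so the E-box — near-orthogonal to both trend and the
pesticide-era pulses — is the least confounded choice, and recovery
scoring treats phase-shift families' driver calls as ambiguous rather
than false.

**What the generator does not emulate:** taxonomic misassignment,
reference-database incompleteness beyond the rank-fallback, DNA
degradation gradients with depth, PCR/sequencing error, lagged or
threshold (non-linear) driver responses, interactions among families
(competition), and autocorrelated *driver* noise at layer scale.
Passing tests therefore demonstrate statistical behaviour under the
stated stochastic model, not robustness to those real-data features.

## Numerical choices

- Permutation p-values always include the observed arrangement
  (Monte-Carlo) or enumerate all orderings when `n! ≤ B` (exact).
- Window ties break toward the longer window, then the earlier start;
  driver-importance ties break alphabetically.
- Per-window p floors use 2/w! for w ≤ 10 (identity and reversal
  always attain the observed |r|).
- z-scoring uses the n−1 denominator; constant series raise.
- Percentages round half away from zero (68.75 → 69), never banker's.
- Bray-Curtis between two all-zero samples is 0 with a warning.
- Seeds: every stochastic step takes an explicit seed; sub-seeds are
  spawned deterministically (`SeedSequence([seed, tag])`), so a run is
  bit-reproducible across platforms.

## Evaluation scales and limitations

The benchmark (`analysis/07`, `scripts/acceptance.py`, and the
acceptance tests) runs the planted-recovery study over 20 seeds at
2,999 permutations and the null calibration over a few hundred
global-null replicates at reduced driver scope (one climate + one
biocide series, 999 permutations); these sizes keep a full evaluation
in the tens of minutes on one CPU while leaving Monte-Carlo error well
below the decision margins.

Known limitations, quantified by the benchmark rather than hidden:

- **Exchangeability.** Permuting a driver series destroys its
  autocorrelation, so permutation p-values are mildly anti-conservative
  for smooth, trending drivers against persistent families.
  Block/circular permutations are deliberately out of scope; the
  global-null false-call rate (which the acceptance suite checks
  against α + 3 MC sd) remains controlled, but borderline chance
  alignments of family drift with era-structured drivers survive BH
  more often than nominal.
- **Short biocide axes.** On an 18-layer biocide axis, a genuine
  correlation of 0.72 (the attainable realization of r* = 0.8 after
  count-link attenuation) yields a best-case permutation p of about
  5e-4 to 3e-3 — the same order as the BH threshold across 80 tests
  per class at α = 0.05. Biocide-link recovery is therefore
  intrinsically borderline: the benchmark measures link recall ~0.75
  and precision ~0.7 against the planted truth, versus near-complete
  recovery of climate-axis links. This is a property of the study
  conditions (series length, effect size, count noise, test
  multiplicity), not of the implementation; the acceptance suite
  reports the measured values without adjustment.
- **Selection optimism in reporting.** The best-window r shown with a
  call is still a maximum over windows and overstates the underlying
  correlation; only the scan-level p is calibrated.
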