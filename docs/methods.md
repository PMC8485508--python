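# Methods

`gutshift` analyzes longitudinal gut-microbiome perturbation/recovery
experiments of the classic three-arm design — untreated controls (CON),
a broad-spectrum antibiotic course (ABX), and the antibiotic followed by
autologous fecal transfaunation (ABXFT) — sampled densely around a
treatment window (days 0–6, transfaunation on day 7) and sparsely over a
~4-month recovery.  This note documents the models, their assumptions,
the defaults, and what the synthetic-data generator does and does not
emulate.

## Phase conventions

Study day < 0 is *pretreatment*, days 0–6 inclusive are *treatment*, and
everything after day 6 is *recovery* (the transfaunation day 7 belongs to
recovery).  Each animal's *baseline community* is its day −4 sample — the
same material used for transfaunation — with a fallback to the nearest
pretreatment sample when day −4 is missing.  All boundaries are
configurable.

## Preprocessing

Filters follow the usual amplicon-survey conventions with literal
boundary semantics:

- samples with **< 10,000** reads are discarded (a 10,000-read sample is
  kept);
- diversity metrics are computed after rarefaction to **15,000** reads —
  uniform subsampling *without replacement* (multivariate hypergeometric,
  QIIME2 semantics), so retained columns sum exactly to the target;
- for the covariation analysis, in order: pretreatment samples are
  dropped, taxa present in **< 5** samples are removed, features are
  collapsed to genus (features unresolved at genus keep their deepest
  resolved rank, labelled `<rank>__X (unresolved)`), and genera holding
  **< 0.01%** of total counts are folded into `Other`.  The fraction of
  counts removed is logged; on realistic tables it is well under 1%.

The covariation analysis runs on *unrarefied* counts: the Dirichlet
resampling below models depth noise directly, so discarding reads first
would only lose information.  A rarefied variant is a caller choice
(rarefy first, then build instances).

Whether the 0.01% low-abundance fold should be assessed before or after
genus collapsing is genuinely ambiguous; it is applied after collapsing
(matching the order in which the filters are described), and the
threshold is a parameter.

## Sequencing noise: Dirichlet Monte-Carlo CLR instances

Counts are compositional: only relative information is meaningful, and a
finite read depth adds multinomial noise.  Both are handled ALDEx2-style:
for each animal's series and each of `n_instances` (default 128)
replicates, a composition is drawn per timepoint from
Dirichlet(counts + 0.5) — the 0.5 is a Jeffreys-style prior that also
resolves zeros — and transformed to centered log-ratios,
clr(x)ⱼ = log xⱼ − (1/D)Σₖ log xₖ, whose per-sample mean is zero by
construction.  Downstream inferences are pooled over instances, so
reported uncertainty includes sequencing-count uncertainty.

## Diversity

- **Shannon–Weaver** alpha diversity defaults to log base 2 (bits); the
  classical natural-log variant is exposed via `log_base` and the base is
  recorded in the output name.
- **Unweighted UniFrac** is computed from the rooted phylogeny by an
  edge-presence matrix: a branch belongs to a sample when any descendant
  leaf has count > 0 (presence is assessed after rarefaction, the only
  scale on which presence is comparable); the distance is unshared branch
  length over branch length in either sample's spanned set.  The
  implementation is validated exactly against a brute-force per-edge
  enumeration oracle and cross-checked against scikit-bio.  A normalized
  weighted variant is provided as a secondary metric.
- **Distance from baseline** reads each sample's UniFrac distance to the
  animal's baseline column — the recovery trajectory's response variable.
- **PCoA** is classical metric MDS (scikit-bio backend).
- The baseline group comparison is a Kruskal–Wallis rank test.  Because
  pretreatment samples within an animal are temporally autocorrelated,
  the bundled analysis feeds per-animal baseline means (animals as
  independent units) rather than raw samples.

## Trajectory smooths and group contrasts

Diversity responses are modelled as
y = f_group(day) + b_animal + ε with penalized cubic B-spline smooths
per experimental group (10 interior knots at day quantiles,
second-difference penalty, smoothing parameter by GCV on a log grid) and
animal-level intercepts under a light ridge (default 10⁻³) that both
regularizes the repeated-measures structure and resolves the
level-splitting indeterminacy between a group's smooth and its animals'
offsets.  The fidelity term is weight-normalized, so duplicating
observations (or equivalently doubling all weights) leaves the fit
unchanged at fixed penalty.  Pointwise 95% bands come from the penalized
regression covariance.

Group contrasts use a permutation test: the statistic is the integrated
squared difference between two fitted group curves over the common day
range; the null distribution permutes group labels **across animals**
(animals, not samples, are the exchangeable units of this repeated-
measures design), refitting at the smoothing parameter chosen on the
observed data; p = (1 + #{perm ≥ obs})/(1 + n_perm).  This reproduces
the scientific contrasts of a hierarchical-GAM analysis without relying
on parametric t/F reference distributions.  Contrasts can be restricted
to a phase window, supporting the stepwise whole-study / per-phase
testing pattern.

Measured operating characteristics (200 simulations, 199 permutations,
5 animals/group; see `scripts/acceptance.py`): type-I error ≈ 2% at
α = 0.05, power ≈ 98% for a persistent 2-SD group offset.

## Covariation engine

The core inference treats each animal's CLR series Y (D taxa × T
timepoints at days t) as matrix-normal with unknown row (taxon)
covariance Σ and known column covariance
K = k_SE(t, t; ℓ) + λI, a squared-exponential kernel that absorbs the
irregular temporal spacing and autocorrelation.  Defaults: lengthscale
ℓ = 10 days — wide enough to correlate the dense 2-day samples while
leaving the weekly-to-monthly tail nearly independent — and nugget
λ = 0.1.  The mean is a per-taxon constant (row mean): the covariance,
not the mean, is the inference target, and K already absorbs smooth
temporal structure.

With an inverse-Wishart prior Σ ~ IW(ν, Ξ) (defaults ν = D + 3, Ξ = I:
weakly informative with a proper mean) the posterior is conjugate:

    Σ | Y ~ IW(ν + T, Ξ + (Y − M) K⁻¹ (Y − M)ᵀ)

Per instance, `n_posterior_draws` (default 50) draws of Σ are converted
to correlation matrices and pooled across Dirichlet instances and across
the animals of a group — animals are biological replicates, and pooling
correlation draws approximates a group-level posterior without inventing
a hierarchical prior.  Conversion-to-correlation happens *before*
pooling.  Pairs whose 95% equal-tailed credible interval excludes zero
are *significant*; pairs with |median ρ| strictly above 0.5 are *strong*
("in excess of" 0.5).  The two flags are stored independently.

Numerical notes: K is Cholesky-factorized (a non-positive-definite K —
duplicate days with zero nugget — raises with guidance to set a nugget);
posterior draws use `scipy.stats.invwishart`; every correlation draw is
symmetric with unit diagonal and eigenvalues ≥ −10⁻⁸.

Measured operating characteristics (20 seeds each): on null data
(diagonal truth, D = 20, T = 15, 3 animals, 32 instances) well under 10%
of pairs are flagged significant; with |ρ| = 0.8 planted on 8 disjoint
pairs (D = 30, 5 animals) strong-edge sensitivity is ≈ 0.8 with no sign
flips.  Sensitivity is limited by prior shrinkage (the Ξ = I diagonal
adds one unit to each scale entry) and by CLR/count noise; a planted 0.8
typically posts a median near 0.6.

`log_ratio_trajectory` summarizes one taxon's CLR across instances per
day (2.5/25/50/75/97.5 percentiles) and classifies the treatment-phase
trend (rising/flat/falling) — the signature by which antibiotic-
resistant taxa (*Bacteroides*-like) reveal themselves while the rest of
the community crashes.

## Resistome summaries

ABR gene tables (gene × sample counts, a gene→family map over
Tetracycline / Beta-lactam / Aminoglycoside / Macrolide / Vancomycin /
MDR / Sulphonamide, families outside the set mapping to Other, and
per-sample total reads) are summarized as per-sample family proportions,
ABR relative abundance (gene reads over total reads; the denominator
choice is configurable), group × day means ± SEM over animals
(single-animal cells report a missing SEM), and a pre → treatment →
recovery trend classification with a 5% relative tolerance so sampling
wobble is not called a trend.  The cross-sectional view relates
per-animal ABR load to lifetime antibiotic exposure; the permutation
Spearman test attached to it is a quantitative extension of an analysis
that is, at n = 6, intrinsically qualitative.

## Synthetic-data generator

The generator inverts the analysis model so every stage has a planted,
recoverable ground truth:

- Latent log-abundances per animal are matrix-normal: row covariance
  `latent_sd² ×` a planted correlation matrix (identity plus disjoint
  strong pairs by default), column covariance a squared-exponential
  kernel over the sampling days (default lengthscale 10 days, smooth
  multi-week dynamics).  Counts are multinomial through a softmax at a
  depth drawn uniformly from `depth_range` (default 15,000–60,000), i.e.
  a logistic-normal/multinomial model — chosen over
  Dirichlet-multinomial because the analysis measures covariance on the
  CLR scale, which the logistic-normal parameterizes directly.
- Per-taxon baseline log-means (SD 1.25) give realistic unevenness.
- The antibiotic crash subtracts `perturbation_effect` (default 4.0
  natural-log units, ~55× reduction) times a unit-mean gamma(2, 0.5)
  per-taxon susceptibility multiplier from non-resistant taxa during
  days 0–6, decaying exponentially at the group recovery rate
  afterwards.  Heterogeneous susceptibility matters: a uniform shift is
  nearly compositionally invariant and would neither crash diversity
  nor push taxa below detection.  Resistant taxa are untouched, so
  their CLR rises during treatment.
- Transfaunation is a convex blend (weight 0.5) of the latent state with
  the day −4 state from day 7 onward.  No quantitative engraftment model
  exists to calibrate against; the weight is a free parameter, not an
  estimate.  A side effect worth knowing: the shared baseline component
  induces extra taxon-taxon covariation in ABXFT animals.
- The resistome table draws ~83 genes across seven families with a
  baseline mix dominated by Tetracycline (~51%) and Beta-lactam (~30%);
  treated samples multiply total ABR abundance (default 2×) and the
  Beta-lactam family weight (default 3×) during the window, decaying in
  recovery.
- Default cohort: CON 6, ABX 3, ABXFT 2 animals; sampling days −6, −4,
  −2, 0, 2, 4, 6, 8, 10, 13, 20, 34, 62, 90, 118.
- All outputs are deterministic in (design, truth, seed); the latent CLR
  states can be exported (`export_latent=True`, off by default) for
  ground-truth checks.

What the generator does **not** emulate: read-level artifacts (chimeras,
sequencing error), realistic taxonomies or phylogenetic signal in the
correlation structure, diet/season covariates, and cross-animal
transmission.  Passing tests therefore demonstrate that the pipeline
recovers the statistical structure it assumes — smooth latent dynamics,
planted correlations, phase-locked enrichment — not that real gut
communities satisfy those assumptions.

## Problem sizes used in the bundled studies

Simulation studies run at the sizes stated above (20 seeds for
calibration/recovery, 50 seeds for signature fractions, 200 × 199 for
the permutation-test error rates); the end-to-end demo uses 8 animals ×
15 days × 40 taxa with 16 Dirichlet instances and 25 posterior draws.
These sizes were chosen so the whole suite re-runs in minutes on one
core while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- The permutation contrast fixes the GCV smoothing parameter at its
  observed-data value during permutations (standard practice; slightly
  conservative in our measurements).
- Pooling correlation draws across animals is an approximation to a
  hierarchical model; with very few animals the pooled interval mixes
  between- and within-animal uncertainty.
- The inverse-Wishart prior shrinks strong correlations noticeably at
  T = 15; users with longer series can lower `prior_dof` toward D + 2.
- CLR induces a weak negative dependence (−1/(D−1)) between unrelated
  taxa; at D ≥ 20 this is negligible relative to posterior spread.
- The click CLI reports errors with click's standard exit codes (0
  success, non-zero failure) rather than distinguishing user from
  internal errors.
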