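# Methods

This note documents the statistical models, numerical choices and known
limitations of `gutsem`, in the order the pipeline applies them.

## Screening and demographics

Exclusion rules are applied in a fixed order — non-Japanese, pregnant or
lactating, enema stool, antibiotics within 3 months, questionnaire
non-response — and a participant failing several rules is counted once,
under the first failing rule, so the audit's removal counts always sum to
the number removed. A missing flag is treated as non-response. Controls
require both the absence of any current illness or treatment and a CES-D
score strictly below 16; a score of exactly 16 already flags suspicion of
depression, so such participants stay unassigned. Age and BMI are compared
by Welch's unequal-variance *t*-test; CES-D by the two-sided Wilcoxon
rank-sum test (exact enumeration when both groups have n ≤ 25 and no ties,
otherwise the normal approximation with tie correction).

## Coverage-based rarefaction

For one sample with depth N and genus counts N_i, the expected richness of
a random subsample of n reads is the hypergeometric expectation
E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n)), evaluated with log-gamma arithmetic.
The *rarefaction slope* at n is the forward difference E[S_{n+1}] − E[S_n]:
the expected number of new genera the next read would reveal. Each sample is
subsampled without replacement (multivariate hypergeometric) to the smallest
depth at which the slope is ≤ 0.002259329 (the coverage threshold the
workflow standardises on); the smallest such depth is found by binary search,
valid because the slope is non-increasing in n. Samples whose slope still
exceeds the threshold one read short of full depth are excluded and logged.
The slope is defined here as a discrete forward difference; an analytic
derivative of the rarefaction curve differs by O(1/N), which the exhaustive
enumeration tests bound at small depths. Genera left with zero counts in
every retained sample are dropped. The target depth is a deterministic
function of the counts; only the identity of retained reads depends on the
seed.

## Dirichlet Monte-Carlo CLR

Counts are compositional, so analysis happens on centered log-ratios. For
each sample, `n_instances` (default 128) probability vectors are drawn from
Dirichlet(counts + prior) with a uniform prior mass of 0.5 per taxon — the
conventional choice that also resolves zeros — and each draw is mapped to
clr(p)_i = log p_i − mean_j log p_j. The Dirichlet draw is realised through
independent Gamma variates; their normalising constant cancels inside the
CLR. The element-wise median across instances is the point summary used for
SEM fitting and factor scoring.

## Effect-size screening

The per-genus effect of group membership is a standardized signal-to-noise
ratio computed inside each Monte-Carlo instance: with P = max(n_case,
n_control) random case/control pairings, effect = median(case − control) /
max(median |case − case'|, median |control − control'|), and the reported
effect is the median over instances. The sign convention is case minus
control. The per-group pairing streams are seeded from the group
*membership* (sorted sample indices), which makes the estimator exactly
antisymmetric under swapping the group labels at the same seed. A dense
oracle — full pairing enumeration over thousands of instances — bounds the
random-pairing approximation at ±0.1 in the tests. Expected Wilcoxon p and
Benjamini–Hochberg q values are means of the per-instance quantities.
Genera with effect > 0.2 (more abundant in cases) or < −0.2 (less abundant)
become SEM candidates; the threshold is strict, and an effect is a
dimensionless ratio, so it is comparable across sequencing depths.

At the target cohort sizes (≈ 35 cases) the sampling noise of the effect
statistic is ≈ 0.15 SD per genus, so a |effect| > 0.2 screen unavoidably
admits false-positive genera alongside truly shifted ones. This is a
property of the design, not the implementation; the SEM pruning stage is
the mechanism that subsequently discards indicators that do not cohere.

## Beta diversity

PERMANOVA partitions squared Bray–Curtis distances: F = (SS_between/(g−1)) /
(SS_within/(n−g)) with SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij; the p-value
is the add-one permutation estimator (1 + #{F* ≥ F})/(1 + n_perm), which can
never return 0. PERMDISP embeds the distance matrix by principal
coordinates, keeps negative-eigenvalue axes with the imaginary-part
convention (their squared contributions are subtracted), measures each
sample's distance to its *group centroid* — the reference R implementation
defaults to spatial medians, a documented divergence chosen for a
closed-form test surface — and permutes the dispersion values' group
labels under a one-way ANOVA F. Numerically negative squared distances to
a centroid are clamped to zero with a warning. NMDS minimises Kruskal
stress-1 by SMACOF with isotonic regression; the library default is 20
random starts, 500 iterations, tolerance 1e-7, while the orchestrated
pipeline uses 2 random starts plus a principal-coordinates start with 150
iterations — at n ≈ 400 the full setting costs minutes for an exported
ordination whose stress (≈ 0.3) is too high to interpret anyway, which is
itself the realistic outcome for cohorts of this kind.

## Structural equation model

**Model.** Candidate taxa more abundant in cases load on latent factor lv1,
less-abundant taxa on lv2 (a latent left with a single indicator is demoted
to a directly observed predictor). Latents, and any direct predictors, are
wired to a latent depression liability y*; the observed label is y = 1 iff
y* exceeds a probit threshold τ fixed at its univariate estimate
Φ⁻¹(1 − prevalence) (standard two-step categorical-SEM practice).

**Moments.** Indicators are z-scored (constants recorded for later blinded
scoring). The sample moment vector holds Pearson correlations among
indicators and two-step polyserial correlations between each indicator and
the binary outcome, rho = r·√(p(1−p))/φ(τ̂), clipped to ±0.999, with
delta-method asymptotic variances. Weights are expressed on the
per-observation scale (the variance of √n·s) so that χ² = (n−1)·F_min is
chi-square distributed with the model's degrees of freedom when the model
holds — a convention verified empirically by the recovery experiments.

**Estimation.** DWLS minimises F(θ) = Σ_k (s_k − σ_k(θ))²/w_k by L-BFGS-B
from a spectral start (leading eigenvector of each latent's indicator
correlation block). Identification: latent variances fixed at 1, so
loadings are standardized and residual variances derive as θ_j = 1 − λ_j²;
exogenous covariances (latent–latent, latent–direct, direct–direct) are
free. The structural disturbance of y* has unit variance and paths are
estimated on that raw scale — the scale on which the synthetic generator
draws data, so recovery is direct — while standardized paths divide by the
implied SD of y* and are the quantities displayed and optimised. Sign
indeterminacy is resolved by forcing the largest-|λ| loading of each latent
positive. Fit indices: GFI = 1 − F_min/F₀ with F₀ = Σ s²/w, AGFI =
1 − (m/df)(1 − GFI), RMSEA = √(max(χ²−df, 0)/(df(n−1))). Saturated models
(df = 0, e.g. a single direct predictor) are permitted: GFI = 1, RMSEA = 0,
AGFI undefined.

**Pruning.** Starting from the full candidate model, greedy backward
elimination removes one variable at a time; a move is feasible when the fit
converges with GFI ≥ 0.90 and RMSEA ≤ 0.08 (conventional cutoffs for
"close to 1"/"close to 0"; configurable) and no structural path sits on its
optimisation bound — without the bound guard, a latent with vanishing
loadings can reproduce the outcome correlations through an arbitrarily
large raw path and hijack the objective. Among feasible moves the one
maximising the largest |standardized path| is taken; the search stops when
no move improves it, and the full trace is persisted for audit. An
exhaustive-subset mode exists for ≤ 10 candidates to validate the greedy
search on small problems.

**Scoring.** The measurement submodel (loadings, residual variances, latent
correlations, z-scoring constants — nothing about the outcome) produces
empirical-Bayes factor scores ξ̂ = ΨΛᵀ(ΛΨΛᵀ + Θ)⁻¹z; direct predictors pass
through as standardized values. Scores are bit-identical whether or not an
outcome column is present.

## Risk model

SMOTE grows the minority class to parity with the majority by interpolating
between each minority point and one of its k = 5 nearest minority
neighbours (Euclidean distance on internally standardized features;
interpolation in the original space); majority rows and original minority
rows are preserved verbatim. Logistic regression is fitted by iteratively
reweighted least squares with a tiny ridge (1e-6, intercept unpenalised)
that keeps separable fits finite. Cross-validation is stratified 10-fold
with SMOTE applied *inside each training partition only* — never to
held-out data — a leakage-free scoping choice; held-out probabilities are
pooled into the headline ROC (per-fold AUCs and the resubstitution AUC of
the final full-data refit are also reported, since either convention
appears in applied work). The deployable bundle (measurement submodel +
logistic coefficients + standardization constants) is one JSON file that
scores new count tables without outcome information.

## Synthetic cohorts

The generator emulates the cohort structure this analysis targets: two sex
strata with case:control imbalance 33:246 and 35:384; genus counts drawn
Dirichlet-multinomial (total concentration 50) around a log-normal baseline
profile (SD 1.5 on the log scale, sorted so taxon index doubles as
abundance rank); depths uniform in 2,300–34,000 reads; age/BMI/CES-D drawn
from the group summaries of the emulated population, with control CES-D
truncated below the screening cutoff of 16; optional participants failing
screening rules or the control criteria exercise the screening stage.
Planted case/control differences are additive shifts on log-abundance
before compositional closure, so their realised CLR effect is *attenuated*
relative to the planted shift and is verified against the Monte-Carlo
oracle rather than assumed: the study-conditions configuration
(`study_config`) uses shifts of 0.5–0.7 (up) and 0.9–1.0 (down) on
abundance ranks 5–44, sized once so realised effects land near 0.25–0.6. A
`latent_scale` knob (0.7 in the study configuration) adds a shared
per-sample community factor over each planted set in cases and controls
alike, inducing the within-group indicator correlations the latent-variable
model assumes. A separate generator draws indicator/outcome data directly
from a one-factor SEM (ξ ~ N(0,1), x_j = λ_jξ + ε_j, y* = γξ + ζ,
ζ ~ N(0,1)) for parameter-recovery experiments.

What the generator does **not** emulate: taxonomic tree structure, read- or
ASV-level noise, batch effects, covariate–microbiome dependence, and the
long tail of hundreds of very rare genera in real tables (120 taxa by
default). Consequently, passing tests demonstrate the pipeline's internal
correctness and calibration under its own assumptions, not clinical
validity of any fitted model; post-rarefaction depths also come out lower
than in real data because coverage depends on the simulated richness.

## Degenerate inputs and numerical conventions

All randomness flows through seeded NumPy generators; the pipeline spawns
per-stage seeds from one master seed and two runs with the same inputs and
seed are byte-identical. Within-group dispersions are floored at 1e-12 so
effects stay finite on degenerate groups; DWLS weights are floored at 1e-6;
polyserial correlations are clipped to ±0.999; factor-score residual
variances are floored at 1e-8 before inversion. Empty samples, all-zero
samples, single-class outcomes, constant or duplicated indicator columns,
groups of size one, and minority classes smaller than two raise informative
errors rather than propagating NaNs.

## Known limitations

- The effect-size screen's false-positive admissions at realistic case
  counts (see above) mean the SEM candidate lists are noisy by design.
- No robust or mean-and-variance-adjusted χ² variants and no standard
  errors on loadings; point estimates plus fit indices serve the pipeline.
- PERMDISP uses centroids, not spatial medians.
- The full weight-matrix WLS estimator and BIOM input are out of scope.
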