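# gutsem

Sex-stratified depression-risk estimation from genus-level gut-microbiota
profiles.

Cross-sectional 16S cohort studies repeatedly find that the gut microbiota of
people with depression differs from that of healthy controls, but the
affected genera disagree between studies, effect sizes are modest, and
cases are heavily outnumbered by controls. `gutsem` implements a complete,
reusable analysis chain for this setting:

1. **Participant screening** — rule-based exclusions (nationality,
   pregnancy/lactation, enema stool, recent antibiotics, non-response),
   group assignment (physician-diagnosed depression vs. healthy controls
   with CES-D < 16), and a demographic comparison table (Welch's *t* for
   age/BMI, Wilcoxon rank-sum for CES-D).
2. **Compositional preprocessing** — coverage-based rarefaction (each sample
   subsampled to the smallest depth at which the expected number of new
   genera per additional read drops to ≤ 0.002259329) and Dirichlet
   Monte-Carlo centered-log-ratio (CLR) transformation,
   `clr(p)_i = log p_i − (1/D) Σ_j log p_j`.
3. **Diversity report** — Shannon/Simpson/Pielou α-diversity; Bray–Curtis
   β-diversity with PERMANOVA and PERMDISP permutation tests (9999
   permutations, add-one *p* estimator) and non-metric MDS.
4. **Effect-size screening** — ALDEx2-style standardized effects per genus:
   median between-group CLR difference divided by the larger within-group
   dispersion, medianed over Monte-Carlo instances; genera with
   |effect| > 0.2 become candidate indicators ("more"/"less" abundant).
5. **Structural equation model** — candidate taxa load on latent community
   factors (lv1 "positive-effect", lv2 "negative-effect") wired to a
   probit-thresholded depression liability; estimated by diagonally
   weighted least squares (DWLS) on a mixed Pearson/polyserial correlation
   matrix; backward indicator pruning keeps GFI ≥ 0.90 and RMSEA ≤ 0.08
   while maximising the dominant structural path.
6. **Blinded risk scoring** — the measurement submodel alone produces
   empirical-Bayes factor scores `ξ̂ = ΨΛᵀ(ΛΨΛᵀ + Θ)⁻¹ z` without ever
   seeing the outcome; a logistic model on those scores, trained with SMOTE
   balancing inside stratified 10-fold cross-validation, yields a deployable
   depression-risk estimator summarised by its pooled held-out ROC/AUC.

Because cohort data of this kind are typically not shareable, the package
ships a first-class synthetic-cohort generator
(Dirichlet-multinomial counts around a log-normal baseline, planted CLR
effects, Table-1-style covariates) so the entire pipeline is testable and
reproducible end to end.

## Worked example

```python
from gutsem import PipelineConfig, generate_cohort, run_pipeline
from gutsem.simulate import study_config

cohort = study_config(seed=7)                   # 35 cases / 384 controls,
counts, meta, roster = generate_cohort(cohort)  # 5 planted differential genera

config = PipelineConfig(out_dir="demo_out", sex="female", seed=11, n_perm=999)
result = run_pipeline(config, counts=counts, roster=roster)
print(result.sem_fit.summary())
print(result.risk.summary())
```

which prints

```
Structural equation model (DWLS on mixed correlations)
  n = 412, moments = 3, free parameters = 3, df = 0
  chi2 = 0.000, GFI = 1.000, AGFI = nan, RMSEA = 0.000
  outcome threshold tau = 1.373
  Loadings (standardized):
    lv1 =~ Genus_012: lambda = +0.704, theta = 0.505
    lv1 =~ Genus_023: lambda = +0.499, theta = 0.751
  Structural paths (standardized | raw):
    lv1 -> depression: +0.494 | +0.568
Logistic depression-risk model (SMOTE-balanced, 10-fold stratified CV)
  intercept = -0.476; lv1: +1.639
  pooled held-out AUC = 0.726 (per-fold mean 0.756); resubstitution AUC = 0.732
```

Reading this: pruning reduced the candidate taxa to a single latent factor
measured by two planted genera (standardized loadings 0.70 and 0.50), whose
standardized path to the depression liability is +0.49; the factor scores
feed a logistic model whose pooled held-out AUC is 0.73 — the planted signal
is recovered and the risk model discriminates well above chance (0.5). All
intermediate artifacts (screening audit, rarefied table, effect sizes, SEM
search trace, ROC points, deployable model bundle) are written to
`demo_out/`. New samples can be scored, outcome-blinded, with
`gutsem score --model demo_out/risk_model.json --counts new.tsv --out risk.tsv`.

The same workflow is available from the shell:

```sh
gutsem simulate --out-dir sim --seed 7
gutsem run --counts sim/counts.tsv --roster sim/roster.tsv \
           --out-dir demo_out --sex female --seed 11
```

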