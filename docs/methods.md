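# Methods

This note documents the statistical models implemented in `ncflow`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make every run
reproducible.

## Data model

An `Experiment` is a probes × samples matrix of non-negative integer
counts with a probe annotation (class: endogenous, housekeeping,
biological positive control, positive spike, negative spike; spike
concentration in fM for the positive spikes) and per-sample metadata
(lesion group, cartridge, covariates, lane attributes). The biological
positive controls are an *annotation overlay* on endogenous biology: they
participate in every endogenous analysis (they can be, and in the colon
panel often are, differentially expressed) while additionally driving the
missingness flag.

## Quality control

Stages run in a fixed order; a sample's exclusion records the first stage
that flagged it.

1. **Technical flags.** IMAGING when counted/attempted fields of view
   < 0.75; BINDING when binding density leaves [0.1, 2.25] spots/µm²; LOD
   when the 0.5 fM positive spike does not exceed mean + 2 SD of the
   sample's negative controls. These cutoffs follow the platform's
   published guidelines (the named checks come without numbers in most
   study reports) and are all exposed in `QCConfig`. The SD uses the
   population convention (ddof = 0) so a single negative probe still
   yields a finite cutoff.
2. **PCA outliers.** On `log2(count + 1)` over the biological probes
   (endogenous + biological positives + housekeeping — QC precedes
   normalization, so raw counts are used), each probe is centered across
   samples and the first two principal components are taken. A sample is
   an outlier if its score on either component lies outside
   [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with quartiles by linear interpolation
   (type 7). The fence rule is the deterministic replacement for the
   visual confirmation step a human analyst would apply; it is applied
   once (not iterated after removal) to the technically passing samples.
   An absolute tolerance of `1e-8 × max|score|` guards zero-variance axes
   so identical samples are never flagged.
3. **Biological missingness.** The background threshold is the arithmetic
   mean of the sample's negative-control counts. A sample is flagged when
   ≥ 4 of the 11 tissue-specific positive-control genes count *strictly
   below* that threshold; ties count as detected, which is the
   retention-friendly reading. With an 11-gene panel the count rule and
   the >30 % fraction rule coincide for all twelve possible counts, and
   both are carried in `QCConfig` so the equivalence is testable.

The standard missingness rule (> 30 % endogenous AND ≥ 20 % housekeeping
below background; an OR variant is available behind `std_rule`) is
computed for every sample for comparison but does not drive exclusion.

## Normalization

* **nSolver-style scaling.** Per sample *i*: positive factor
  `f_i = mean_j(p_j)/p_i` with `p_i` the geometric mean of the positive
  spikes; counts are scaled by `f_i`; the scaled negative-control mean is
  subtracted (floored at 0.5 counts); housekeeping factor
  `g_i = mean_j(h_j)/h_i` with `h_i` the geometric mean of the
  background-subtracted housekeeping counts; output is
  `log2(x + 1)`. Zeros are floored at 0.5 before any geometric mean or
  log. A sample whose positive spikes (or background-subtracted
  housekeeping counts) are all at the floor is reported non-normalizable
  rather than silently clamped.
* **RUVg-style factor analysis.** On the samples × probes matrix
  `Y = log2(count + 1)`, the housekeeping columns are centered and
  decomposed by SVD; `W` holds the first *k* left-singular vectors scaled
  by their singular values, `α` the least-squares loadings of all probes
  on `W`. The spike-in probes are *not* used as controls and are excluded
  from the normalized output. `k` defaults to 1 (smallest model; a
  config parameter for sensitivity runs). Differential expression uses
  `W` as design covariates — the recommended mode for downstream
  inference — while the subtracted matrix `Y − Wα` serves visualization
  and correlation outputs. Sign convention: each `W` column's
  largest-magnitude entry is positive, making the decomposition
  deterministic.
* **Negative-binomial size factors.** `c_i` = geometric mean of the
  positive spikes, `λ_i` = mean of the negative controls (identical to
  the QC background threshold by construction), `d_i` = geometric mean of
  the background-subtracted housekeeping counts; `c` and `d` are rescaled
  to geometric mean 1 across samples.

No RNG exists anywhere in this module; all three methods are
deterministic functions of the input.

## Differential expression

Designs are intercept + one indicator per non-referent group (TA is the
conventional referent) + optional numeric/binary covariates + optional
`W` columns; full rank is verified and collinear columns are named.
Covariate adjustment (lesion size, age, sex) is supported but off by
default — in this setting adjusted and unadjusted analyses have been
observed to agree, and the unadjusted model is the primary one.

**Moderated linear model.** Per-gene OLS on the log2 matrix gives
`β̂_g` and `s²_g` on `d = n − p` df. The empirical-Bayes prior
`s²_g ~ s₀²·χ²_{d₀}/d₀` is fitted by moment matching on `log s²`
(digamma/trigamma inversion, Newton iteration for the trigamma inverse);
when the observed spread of `log s²` does not exceed the χ² sampling
spread, `d₀ = ∞` and all variances shrink to `s₀²` (handled as the
normal limit). Moderated variances
`s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d)`; the moderated t per contrast uses
the design-based unscaled variance and a t reference on `d₀ + d` df,
two-sided. Contrasts are tested one coefficient at a time within the
joint three-group model.

**Joint NB model.** `E[Y_ig] = λ_i + c_i d_i μ_ig`, `log μ_ig = x_iᵀβ_g`.
The background enters as a subtracted offset — counts are replaced by
`max(Y − λ_i, 0)` and `log(c_i d_i)` enters as a GLM offset — rather
than through a full Poisson-convolution likelihood; this simplification
preserves the three-factor normalization and the NB/empirical-Bayes
structure while keeping the likelihood standard. Per gene: Fisher
scoring (IRLS with step halving) for `β` at fixed dispersion; profile-ML
dispersion `φ_g` by bounded scalar minimization over `log φ ∈
[log 1e−6, log 10]`; shrinkage on the log scale toward the across-gene
mean, `log φ̃_g = w·mean(log φ) + (1 − w)·log φ_g` with
`w = n₀/(n₀ + n)` and prior weight `n₀ = 10` — a global shrinkage
target, since a few hundred genes are too few to fit a stable
mean–dispersion trend. Each group coefficient is tested by a 1-df LRT at
the shrunk dispersion. Genes that fail to converge are reported with NA
statistics and excluded from the BH denominator, with the count carried
on the result.

**Multiple testing.** Benjamini–Hochberg step-up; ties in p receive
equal q; q is capped at 1. Significance is `q < 0.05` by default.
Fold changes are log2: directly for the linear engine, `β/ln 2` for the
NB engine.

## Evaluation

Fold-change correlations are Pearson over the shared tested genes with
pairwise NA exclusion. DEG overlaps are exact Venn-region counts over
every non-empty method subset on the common gene universe.

The **Type I simulation** permutes the group labels uniformly at random
(optionally stratified by cartridge; unstratified is the default, as the
labels are exchangeable marginally), re-runs the *entire* normalization +
DE pipeline on the permuted labels, and records the fraction of
endogenous-class genes with unadjusted p < α, pooled over the group
contrasts. One master seed spawns per-replicate child seeds (recorded in
the result), so runs are bit-reproducible end to end. On the synthetic
null the two moderated-linear pipelines are calibrated at α = 0.05 to
within Monte-Carlo error; the NB-joint pipeline measured slightly
*conservative* (~0.045) on the same null — the Type I inflation reported
for full-likelihood joint NB implementations on real data is
implementation- and data-dependent and is not reproduced by this
simplified engine.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
not any particular dataset. Defaults define the study conditions:

* **Panel**: 277 endogenous + 15 housekeeping + 11 biological positive
  controls; 6 positive spikes at 128/32/8/2/0.5/0.125 fM with gain
  156.25 counts/fM (≈ 20 000 counts at 128 fM); 8 negative probes.
* **Cohort**: 25 SSL / 27 TV / 48 TA, interleaved proportionally into
  cartridges of 10 study lanes (mirroring stratified randomization);
  sizes/ages/sexes drawn with group-typical moments.
* **Counts**: biological probes are NB (`var = μ + φμ²`,
  `φ ~ U(0.05, 0.15)`) around
  `2^(baseline + group effect + size + batch·loading + composition·loading + degradation + outlier shift)`,
  plus additive Poisson background; spikes are Poisson around
  gain × concentration × lane scale; negatives are Poisson around
  probe-specific affinities with lognormal (right-skewed) spread, so the
  negative-control *mean* sits above the typical nonspecific level of a
  biological probe (set at 0.4 × the negative mean) — as on the real
  platform, where the background threshold is a conservative upper bound.
* **Technical structure** is *bounded*: lane size factors uniform within
  ±0.4 log2, a per-sample tissue-composition axis uniform within ±0.5
  log2 acting through mean-zero N(0, 1) gene loadings (histologic
  composition is the dominant biological-nuisance axis in tissue panels),
  and a small ±0.15 log2 cartridge batch effect with gene-specific
  loadings. Bounded uniforms are deliberate: the QC fence rule is a
  deterministic Tukey screen, and heavy-tailed technical noise would make
  "outlier" an arbitrary label on clean cohorts. What passing QC tests
  on this generator shows is that the screen isolates *planted* artifacts
  without collateral exclusions; it does not show how the fences behave
  under heavy-tailed real-world noise, where the visual-confirmation step
  they replace matters.
* **Degradation** attenuates biological probes only (spikes pass, as for
  real FFPE degradation) by −5 log2 in the preset, uniform across genes
  with an optional per-gene jitter; **outlier lanes** shift every probe
  (spikes included) by +5 log2, like a gross lane-efficiency artifact.
* **The reference preset** (`reference_cohort`) plants 2 outlier lanes,
  11 degraded samples, 39 SSL-vs-TA effects (mucin-program analogs and
  four positive-control genes over-expressed; WNT-program analogs and
  four more controls under-expressed) and 32 TV-vs-TA under-expression
  effects, |log2FC| between 0.4 and 1.1. Effect sizes are moderate on
  purpose, so the genuine group axis ranks below the technical axes that
  the two-component PCA screen examines — in the emulated study the PCA
  step caught technical outliers, not a whole lesion class. Under the
  default QC configuration the preset loses exactly the 13 planted
  samples, leaving 87 for DE.

The generator does not model gene–gene correlation beyond the shared
latent axes, length- or GC-dependent degradation profiles, or wet-lab
purity metrics.

## Problem sizes and numerical conventions

Simulation-backed tests and the acceptance script run at the cohort
scale the workflow targets (≤ 100 samples × ~320 probes) with 200
permutation replicates and a few hundred replicates for
expectation-level FDR checks; a full run of everything completes in well
under a minute on one CPU. Fixed conventions: log2 with pseudocount 1;
0.5-count floor before geometric means and logs; quartiles by linear
interpolation; mergesort (stable) ordering wherever sorting can tie; all
simulation randomness from `numpy.random.default_rng` with explicit
seeds, master seeds spawning recorded child seeds.

## Known limitations

* The NB-joint engine is a faithful simplification of full-likelihood
  joint NB models: background is an offset, not a convolution, and the
  dispersion prior is a global mean without a trend. Its operating
  characteristics (e.g. Type I behavior) therefore need not match any
  specific published implementation.
* The moderated linear engine treats samples as independent; duplicate
  lanes/technical replicates should be excluded before DE (the preset
  does not generate them into the analysis set).
* QC fences are a deterministic stand-in for expert visual review; on
  real data with heavy-tailed noise they may flag borderline clean
  samples, and the IQR multiplier is exposed in `QCConfig` for exactly
  that reason.
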