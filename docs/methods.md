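# Methods

## Study design being modelled

The package operates on nested case–control data: incident pancreatic-cancer
cases identified within prospective cohorts, each matched 1:1 to a
cancer-free control on age at draw (±2 years), sex, cohort, race/ethnicity
and blood-draw date (±90 days).  Plasma miRNA is profiled on a
hybridization-counting panel of 798 endogenous human miRNAs with eight
negative controls, six positive controls and five non-mammalian spike-ins,
three of which (ath-miR159a, cel-miR248, osa-miR414) are added to every
sample at extraction and carry the extraction-efficiency signal.  All
trajectory and prediction analyses are indexed by lead time, the years from
blood draw to the case's diagnosis; the lead time is a property of the case
and is copied to its pair.

## Normalization

Four steps in fixed order, each recorded in the matrix's stage tag and
allowed once:

1. *Background*: per sample, subtract the arithmetic mean of the
   negative-control counts from endogenous and spike-in rows, flooring at
   zero.  The number of negatives used is configurable (all present by
   default).
2. *Spike-in*: per sample s, let m_s be the arithmetic mean of the three
   extraction spike-ins; the factor is geomean_t(m_t)/m_s.  This removes
   extraction/input variation: regressing log spike signal on the true log
   efficiency of the generator recovers slope 1 within ±0.05 at n ≥ 500.
3. *Content*: same construction on g_s, the geometric mean of the 50
   endogenous probes with highest mean count across samples, excluding
   hsa-miR-451a, hsa-miR-16-5p and hsa-miR-320e.  These three are
   red-blood-cell miRNAs: a hemolysed sample inflates them strongly, and
   excluding them keeps its content factor within 1% of the uncontaminated
   value where it would otherwise shift by more than 5%.  The top-50 set is
   defined globally (one shared set), so factors are comparable across
   samples.  Zeros are replaced by 0.5 inside the geometric mean only.
4. *Quantile*: classic rank-mean quantile normalization across samples over
   endogenous rows; ties within a sample receive the mean of the reference
   values their ranks span.

Factor provenance (background levels, spike and content factors, content
set, exclusions) is returned with the normalized matrix and written as JSON
by the pipeline.

Two properties deserve note.  First, scale invariance: multiplying one
sample's raw counts by c > 0 multiplies *every* sample's normalized values
by the single constant c^(1/n) (n = number of samples) because the
references are cross-sample geometric means; every between-sample contrast,
rank and case/control ratio is therefore exactly invariant, and the tests
assert this identity in its exact (zero-background, zero-free) form.
Second, with ties present the tie-averaging rule means sorted vectors after
quantile normalization agree only up to tied positions; the
identical-sorted-vector identity is exact on tie-free data.

## Matched association

Expression is recoded per probe to decile scores 1–10 using the pooled
case+control values of the analysis window (cutpoints at the empirical
10th–90th percentiles, score = 1 + #{cutpoints < value}, so scores are
invariant to any strictly monotone transform of a probe).  Windows default
to (0,5], (5,10], (10,∞) years by the case's lead time, with boundaries
inclusive on the left window.

For 1:1 matching, conditioning on each pair containing one case reduces the
likelihood to L(β) = Πᵢ σ(βᵀΔxᵢ) with Δxᵢ the case-minus-control feature
difference.  The solver is Newton–Raphson with analytic gradient and
observed information, step-halving, tolerance 1e-8 on the score norm, 50
iterations maximum; standard errors come from the inverse observed
information, intervals and p-values are Wald.  Complete separation is
declared at |β| > 15 or a singular information matrix and reported as
non-converged; such fits are excluded from FDR ranking.  The adjustment set
is age, BMI, smoking (never/former/current as two indicators, reference
never), diabetes, and family history.  For paired binary exposure the
estimate reduces to the discordant-pair ratio (OR = a/b), which the tests
exploit as a closed-form oracle, alongside a derivative-free grid/coordinate
search of the (concave) log-likelihood and statsmodels' ConditionalLogit.

Multiple testing uses the Benjamini–Hochberg step-up with an explicit family
size m_total (default: the full 798-probe panel, so filtered or degenerate
probes still count), mapped back to input order; the implementation is
checked exactly against a brute-force oracle and against statsmodels when
m_total equals the vector length.

## Log-ratio trajectories

The pair-level statistic is the natural log of case over control normalized
expression, with a 0.5 pseudocount applied only when either member is zero
(both zero ⇒ 0, flagged).  Per probe, an OLS of log-ratio on lead time
restricted to pairs with lead time ≤ 10 years gives the trajectory slope
per year, its SE and a two-sided t-test; the 10-year cap is inclusive.
Probes partition by slope sign: negative slopes ("rising" pattern — the
case–control gap grows toward diagnosis) versus positive ("falling").

Repeated-draw participants are modelled with a random intercept:
log-ratio_ij = β₀ + β₁·lead_ij + u_i + ε_ij, u_i ~ N(0, σ_u²), fitted by
REML (statsmodels MixedLM).  Random slopes are deliberately omitted — two
to three points per participant cannot identify a slope variance.  On
non-convergence the fit falls back to OLS with cluster-robust standard
errors and says so.

## Risk prediction

Model 1 uses the adjustment covariates; Model 2 adds log CA19-9; Model 3
adds the trend-significant miRNAs (log of normalized value + 0.5); Model 4
adds both.  Coefficients come from the same matched conditional likelihood
(features constant within every pair are dropped with zero weight); a
sample's risk score is the linear predictor, which is all a rank-based AUC
needs.

AUC(t) is cumulative: restrict to pairs whose case has lead time ≤ t and
compute the Mann–Whitney probability that a case score exceeds a control
score over all case × control combinations, ties counting ½ (the
O(n log n) rank-sum identity is used for large sets; both paths are exact).
Internal validation resamples pairs — the pair is the resampling unit —
with replacement, refits all models in-bag and evaluates out-of-bag,
reporting the across-replicate mean and 2.5/97.5 percentile band (B = 500
by default, seeded).  The CA19-9 contribution at horizon t is
operationalized as the share of above-chance AUC lost when Model 4 is
refitted without CA19-9: (AUC₄ − AUC₄₋CA19-9)/(AUC₄ − 0.5); the output
carries this definition string, since "share of discrimination" admits
several formalizations.  Sensitivity filters restrict to early-stage cases
(TNM I/IIA) or to pairs with lead time strictly over 1 year, always
removing whole pairs.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested.  Endogenous counts follow

    count_ks ~ Poisson( b_s + e_s · exp(μ_k + Δ_ks + ε_ks) )

with per-sample background b_s (mean 8 counts), extraction efficiency
e_s = exp(N(0, 0.5)) — a several-fold yield range typical of plasma
extractions — probe baseline μ_k ~ N(4, 1.5) on the log scale, and probe
noise ε_ks.  Case samples of the 13 signal probes receive
Δ = a_k + b_k·min(T, 10): the contrast is linear in lead time up to 10
years and held constant beyond, matching the 10-year fitting window of the
trend analysis.  Slopes b_k are the published per-year trend coefficients
of the 13 trajectory miRNAs; intercepts are set as (published window mean)
− 5·b_k so the simulated 0–10-year mean log-ratio matches the published
means; per-probe noise is the published log-ratio SD divided by √2, making
simulated pair log-ratio SDs (≈1.3–3.2) match the printed ones.  Filler
probes use noise SD 1.2.  Spike-ins scale with e_s under a small technical
SD (0.15); negative controls are pure background; positive controls follow
their nominal titration.  Hemolysis is a per-sample Bernoulli event (3%)
multiplying the three red-blood-cell probes by a log-normal factor (median
8×).  Signal-probe baselines sit at the filler mean so their
lognormal-inflated averages stay below the top-50 content-set cutoff —
otherwise the case–control contrast would leak into the content factors.

Cohort strata default to 290/395/154/468 pairs with covariate prevalences
taken from the control arms of the modelled study (age, BMI, sex, race,
smoking, diabetes, family history per stratum) and case enrichment for
current smoking (odds ×2.5) and diabetes (×2.2) so the covariate model has
non-trivial discrimination.  Lead times follow per-stratum gamma laws tuned
to the published medians (3.7/9.4/6.5/8.2 years) and quartile ratios,
truncated to [0.03, 19.61] years by rejection; a gamma cannot match every
printed quartile exactly (e.g. one stratum's q1 is 6.8 vs 5.9 printed), the
medians are exact.  CA19-9 is a log-normal stand-in — no assay, unit or
timing is being reproduced — with a case shift γ·max(0, 1 − T/τ) on the
log scale; γ = 2.0 and τ = 5 years were calibrated once against the
published Model-2 time-dependent AUC curve (0.79/0.75/0.69 at years 1–3,
0.66 at 5; simulated 0.84/0.76/0.70/0.65).  Stage labels are drawn
independently of lead time (I 12%, IIA 10%, IIB 28%, III 25%, IV 25%).

What the generator does *not* emulate: sequencing-style overdispersion
beyond Poisson–lognormal, storage-duration degradation, cartridge/batch
effects (matched pairs are same-batch by design), correlated miRNA
co-regulation, and real count distributions of any deposited dataset.
Passing tests therefore demonstrate that the estimators recover the
generator's truth under realistic noise magnitudes — not that the published
biological findings would replicate on real data.

## Numerical and design choices

- Natural log throughout; ratio pseudocount 0.5 only for zero-containing
  pairs.
- Decile cutpoints use linear-interpolation percentiles; ties share the
  lower decile; constant probes are flagged degenerate with score 1.
- Deciles are computed within each lead-time window's pooled analysis set,
  keeping the exposure scale window-specific.
- Newton tolerance 1e-8 (score norm), 50 iterations, separation bound 15.
- The bootstrap evaluates out-of-bag rather than a .632-style correction;
  replicates lacking an out-of-bag case pair at a horizon are skipped for
  that horizon and counted.
- Imaging QC metrics (field-of-view ratio, binding density) are instrument
  attributes, not derivable from counts: the QC module evaluates them when
  an attribute table is supplied and otherwise applies the count-based
  flags (positive-control log-linearity R² ≥ 0.95, limit-of-detection
  against mean + 2 SD of negatives).  Default thresholds follow platform
  conventions (FOV ≥ 0.75, binding density 0.1–2.25) and live in
  configuration, never in code.  Samples failing QC are dropped together
  with their pair; with synthetic data there is nothing to re-assay, so
  dropping replaces the wet-lab practice of repeating failed samples.
- Windows: boundary 5.0 belongs to the first window, 10.0 to the second.
- Heavy acceptance simulations are sized to single-CPU runs: the type-I
  study uses 2,000 replicates of 400 pairs with a 16-probe all-null panel
  (the trend test is per-probe, so panel width is irrelevant to its
  calibration), and CI-coverage uses 100 replicates of 300 pairs with a
  60-probe panel.

## Known limitations

- The conditional-logistic module handles 1:1 matching only; k:m sets and
  exact conditional inference are out of scope.
- Trend fits are strictly linear in lead time; no splines or joint
  multivariate trajectory models.
- The AUC estimator is the cumulative/dynamic rank statistic on the matched
  sample; survival-model (Cox-based) time-dependent AUC estimators,
  external validation and calibration metrics are not implemented.
- Whether quantile normalization should precede or follow ratio formation
  is not identifiable from the modelled study's description; this package
  normalizes first and forms ratios second.
- The matched design itself can depress absolute AUC values relative to an
  unmatched population sample; comparisons between nested models are the
  meaningful output.
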