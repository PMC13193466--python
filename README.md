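# mirtraject

Pre-diagnostic circulating-miRNA analysis for matched case–control cohorts:
how do plasma miRNA levels drift in the years before a pancreatic-cancer
diagnosis, and how much do they add to risk prediction?

The package is written for biostatisticians and molecular epidemiologists
working with nested case–control designs: cases and individually matched
cancer-free controls (1:1 on age ±2 years, sex, cohort, race/ethnicity,
blood-draw date ±90 days) drawn from prospective cohorts, with plasma miRNA
profiled on an nCounter-style counting panel (798 endogenous probes,
negative/positive assay controls, non-mammalian spike-ins) and the **lead
time** — years from blood draw to the case's diagnosis — as the central
time axis.

## What it computes

1. **Normalization** of raw probe counts, in the platform's canonical order:
   background subtraction (mean negative-control signal, floored at 0),
   spike-in scaling (arithmetic mean of ath-miR159a/cel-miR248/osa-miR414
   against a cross-sample geometric-mean reference), content scaling
   (geometric mean of the top-50 expressed miRNAs, excluding the hemolysis
   markers hsa-miR-451a/-16-5p/-320e), then rank-mean quantile
   normalization.
2. **Matched association.** Expression is recoded to within-window decile
   scores; for each miRNA and lead-time window ((0,5], (5,10], >10 years) a
   1:1 conditional logistic regression on case-minus-control differences
   estimates the odds ratio per one-decile increase, adjusted for age, BMI,
   smoking, diabetes and family history.  For pair *i* with difference
   vector Δxᵢ the conditional likelihood is L(β) = Πᵢ σ(βᵀΔxᵢ); the fit is
   Newton–Raphson with Wald intervals, and p-values are Benjamini–Hochberg
   adjusted against the full panel size (m = 798).
3. **Log-ratio trajectories.** Per pair, log(case/control) of normalized
   expression; per miRNA, OLS of log-ratio on lead time restricted to ≤10
   years.  Oncogenic markers show negative slopes (the case–control gap
   widens toward diagnosis), suppressors positive — the "scissors" pattern.
   Participants with repeated draws get a random-intercept linear mixed
   model (REML).
4. **Risk prediction.** Four nested conditional-logistic scores — Model 1:
   covariates; Model 2: + CA19-9; Model 3: + trend-significant miRNAs;
   Model 4: everything — evaluated by cumulative time-dependent AUC(t)
   (Mann–Whitney over cases with lead time ≤ t and their controls), with
   out-of-bag bootstrap internal validation and a CA19-9
   share-of-discrimination decomposition.
5. **Synthetic cohorts.** A generator reproduces the whole data structure
   (four cohort strata of 290/395/154/468 pairs, matched covariates,
   cohort-specific lead-time laws, Poisson counts around log-normal means,
   spike-ins, hemolysis artifacts, CA19-9) with known ground truth, so every
   stage is testable end to end without any external data.

## Worked example

```python
import mirtraject as mt

cfg = mt.GeneratorConfig.from_dict({}, seed=1)       # 1307 matched pairs
manifest, counts, truth = mt.generate_cohort(cfg)
normed, factors = mt.normalize_pipeline(counts)

assoc = mt.association_table(normed, manifest)
print(assoc[(assoc.window == "0-5y") & (assoc.p_fdr < 0.05)]
      [["miRNA", "OR", "p", "p_fdr"]].round(4).to_string(index=False))
```

```
                          miRNA     OR      p  p_fdr
                  hsa-let-7i-5p 0.8881 0.0000 0.0156
                 hsa-miR-191-5p 0.8949 0.0001 0.0397
                 hsa-miR-155-5p 1.1109 0.0002 0.0480
hsa-miR-199a-3p+hsa-miR-199b-3p 0.9027 0.0002 0.0480
```

Four of the 798 probes survive panel-wide FDR in the <5-year window — all
true signal probes, with suppressors below OR 1 per decile and the
oncogenic miR-155-5p above.  Continuing with trajectories and prediction:

```python
mirnas = [p.probe_id for p in mt.default_trajectory_panel()]
trend, lines = mt.trend_table(normed, manifest, mirnas)
selected = list(trend.loc[trend.p < 0.05, "miRNA"])
features = mt.build_feature_table(normed, manifest, selected)
grid = mt.auc_curve(features, manifest, selected, horizons=[1, 2, 3, 5, 10])
print(grid.pivot(index="horizon", columns="model", values="auc").round(3))
```

```
model        1      2      3      4
horizon
1.0      0.642  0.839  0.708  0.880
2.0      0.581  0.757  0.620  0.783
3.0      0.565  0.696  0.593  0.720
5.0      0.565  0.653  0.589  0.675
10.0     0.562  0.596  0.576  0.609
```

The full model dominates at every horizon and all curves decline as the
horizon grows: discrimination concentrates in the years just before
diagnosis, driven near t = 1 by CA19-9 and the late-diverging miRNAs.

The same pipeline runs from the shell, stage by stage or end to end:

```bash
mirtraject run --out runs/demo --seed 1          # full chain + report.md
mirtraject simulate --out runs/demo --seed 1     # any single stage
```

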