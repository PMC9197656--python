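# metaprofile

Cross-study screening and standardized-mean-difference (SMD) meta-analysis of
quantitative outcome indicators.

Evidence-synthesis projects that pool study-level summaries across many
publications face a screening problem before any pooling can happen: different
studies report different indicator sets, most indicators appear in only a
handful of studies, and a subjective choice of "which indicators and which
studies" invites selection bias. `metaprofile` implements an objective,
code-driven screening strategy — developed for obstructive sleep apnea (OSA)
trial data, where polysomnography yields hundreds of candidate indicators
(AHI, TST, REM %TST, ODI, ...) — followed by a per-indicator meta-analysis
within each screened subset. It is aimed at meta-analysts and methods
researchers working with long-format extraction tables of per-arm
(mean, SD, n) summaries.

## The method

For a dataset of `T_s` studies, two ratios drive the screening:

- **Indicator coverage ratio** — for indicator *i*,
  `ICR_i = (number of studies reporting i) / T_s`.
- **Study integrity ratio** — under an ICR threshold (ICRT) that retains the
  indicator set `R`, study *s* has `SIR_s = |R ∩ indicators(s)| / |R|`.

Both ratios are cut at threshold grids 0.1, 0.2, …, 1.0 (ICRT and SIRT).
Each (ICRT, SIRT) pair defines a **profile** `P{10·ICRT}-{10·SIRT}` holding
the retained indicators and studies. Within one ICRT a study is assigned only
to its *highest* satisfied SIRT, so profiles at one ICRT partition the
studies; combinations retaining identical indicator and study sets are
collapsed into the highest thresholds; empty profiles are dropped.

Within each profile, every indicator is pooled independently over the
profile's studies with complete baseline/follow-up pairs:

- effect size: Hedges' *g* = `J · (m_f − m_b) / s_pooled` with
  `J = 1 − 3/(4(n_b+n_f−2)−1)`, variance
  `(n_b+n_f)/(n_b n_f) + g²/(2(n_b+n_f))`; follow-up minus baseline, so a
  negative *g* is a decrease;
- inverse-variance fixed-effects pooling; Cochran's *Q*, *I²*, and
  DerSimonian–Laird *τ²*; the random-effects model is used iff the
  heterogeneity test has *p* < 0.05 **and** *I²* > 50%;
- two-sided *z*-test at α = 0.05 with a normal-quantile 95% CI; funnel-plot
  (g, se) data per cell. No multiplicity correction is applied across
  indicators or profiles.

The headline output is an indicator × profile heatmap of pooled SMDs with
nonsignificant cells set to 0 and untestable cells masked, plus a
per-indicator count of profiles with significant decreases/increases.

## Worked example

```
python examples/02_effect_sizes_and_pooling.py
```

prints, for five studies of an apnea-severity indicator:

```
S1: g = -1.196  se = 0.290
S2: g = -1.020  se = 0.258
S3: g = -0.805  se = 0.337
S4: g = -0.715  se = 0.204
S5: g = -0.728  se = 0.298

pooled g = -0.874  95% CI [-1.106, -0.641]
model = fixed  z = -7.36  p = 1.90e-13
heterogeneity: Q = 2.44 (df 4, p = 0.656), I2 = 0.0%, tau2 = 0.0000
=> significant decrease
```

Each study's *g* standardizes the baseline→follow-up change by the pooled SD;
the homogeneous effects (*I²* = 0) keep the fixed-effects model, and the
pooled estimate of −0.87 pooled-SD units is a clear decrease. The other
examples cover screening (`01`), profile construction (`03`), the full
pipeline on a paper-scale synthetic dataset (`04`), and full-scale
reproduction from the separately distributed curated OSA dataset
(`reproduce_deposit.py`). The same stages are available from the shell:
`metaprofile screen|profiles|run|simulate --help`.

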