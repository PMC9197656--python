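# Methods

## Data model

The canonical input is long-format: one row per (study, indicator, arm) with
`mean`, `sd`, `n`, where arm is `Baseline` or `Follow-up`. Long format was
chosen over the wide extraction-sheet layout because it makes missingness
explicit — an absent indicator is an absent row, a missing number is an empty
cell — and `wide_to_long` converts sheets with
`<indicator>_<Baseline|Follow-up>_<mean|sd|n>` column triples. Indicator
names are whitespace-normalized but matched case-sensitively with no synonym
merging: clinically distinct terms (AHI vs AHI-REM) must stay distinct, and
collapsing them is a curation decision, not an I/O default.

Parallel-group studies (control vs experimental arm) are mapped onto the same
two-slot schema — control into the baseline slot, experimental into the
follow-up slot — with the original role kept in an `arm_role` field. Nothing
downstream treats the two designs differently (only per-arm summaries exist
either way); the flag preserves the distinction for anyone who wants to
stratify later.

Missing values (`NA` or empty) are loaded as missing markers and reported,
never dropped silently. A row with an unparseable numeric is kept with the
bad cell set missing and listed in the load report, so a corrupt extraction
cell cannot silently delete a study.

## Screening

`ICR_i = (studies reporting i) / T_s` and, under an ICR threshold retaining
set `R`, `SIR_s = |R ∩ indicators(s)| / |R|`. The SIR denominator is the
*total count of retained indicators* (the textual definition; some notations
print the same quantity under a different symbol). Both grids default to
0.1…1.0 in steps of 0.1.

Design choices that needed fixing:

- **Closed comparisons** (`ICR ≥ ICRT`, `SIR ≥ SIRT`). With an 89-study
  dataset this retains 33 of 284 indicators at ICRT = 0.1 (284 minus the 251
  below 0.1), the count the method's reference analysis reports.
- **Float tolerance 1e-9** on all threshold comparisons: `3 × 0.1 ≠ 0.3` in
  binary, and a 0.1-step grid hits such artifacts constantly. The tolerance
  is far below the resolution of any realizable ratio (multiples of 1/T_s).
- **Histogram bins** left-closed/right-open, last bin closed. With 89
  studies no ratio can land on a decile boundary, so the convention is
  unobservable at full scale, but it is declared and tested.
- **Profile emission**: a profile needs ≥ 1 study and ≥ 1 indicator
  (`min_studies=2` available as the minimum for pooling). Within one ICRT a
  study joins only its highest satisfied SIRT, making the profiles of one
  ICRT a partition of the studies above the smallest SIRT. Additionally,
  combinations whose retained indicator set *and* study set are identical to
  a higher combination's are collapsed into that higher (ICRT, SIRT): they
  would repeat the identical analysis under another name. This collapse is
  forced by the degenerate case (one study, one indicator must yield exactly
  P10-10, not ten copies) and is the declared interpretation of how a 10×10
  grid reduces to the much smaller analyzed set; no closed-form selection
  rule is published for the reference analysis.

## Meta-analysis

Per study, Hedges' g with the small-sample correction
`J = 1 − 3/(4(n_b+n_f−2)−1)` on the independent-two-group contrast
(follow-up − baseline)/s_pooled, variance
`(n_b+n_f)/(n_b n_f) + g²/(2(n_b+n_f))`. The arms are treated as independent
groups because only per-arm summaries are recorded in study-level
extraction; no within-subject correlation is modeled, which makes the
standard errors conservative for truly paired designs. Plain Cohen's d is
available behind `bias_correction=False`.

Pooling is inverse-variance. Heterogeneity: Cochran's Q against chi-square
with k−1 df, `I² = max(0, 100(Q−df)/Q)` (0 when Q = 0), DerSimonian–Laird
`τ² = max(0, (Q−df)/(Σw − Σw²/Σw))`. Model choice is the conjunction rule:
random effects iff `p_Q < 0.05` **and** `I² > 50%`, else fixed. The 95% CI
uses the normal quantile (no Knapp–Hartung adjustment), matching the
convention of the classical meta-analysis routines this pipeline mirrors;
k = 1 results are emitted but flagged (default minimum k for an unflagged
pooled result is 2). α = 0.05 per test with **no multiplicity correction**
across the hundreds of (profile, indicator) cells — by design of the method
being implemented, and worth restating whenever results are interpreted.

Studies missing any of the six numbers for an indicator are excluded from
that one analysis only ("per-cell" exclusion); a study with a zero pooled SD
is likewise excluded from that cell, since the SMD is undefined there.

Funnel data are the untransformed (g, se) pairs per cell.

## Orchestration and outputs

`run_all` is a deterministic function of (dataset, config): profiles are
built, every retained indicator is pooled within every profile, and the
serialized outputs (results table, heatmap, summary, funnel files) use fixed
orderings and number formats so identical runs are byte-identical and input
row order is irrelevant. The heatmap follows the zero-if-nonsignificant
convention; cells with k below the minimum are masked rather than zeroed to
distinguish "not estimable" from "tested, no change". Rows are ordered by
descending coverage, columns by ascending (ICRT, SIRT). The config snapshot
(grids, α, estimator flags, seed) is embedded in the result set and written
to `run.log`.

## Synthetic data

`gen_dataset` draws, per (study, indicator) included by independent
Bernoulli(coverage): a study effect `δ_s ~ N(δ, τ²)`, arm sizes uniform in
the configured range, and observed summaries from the exact sampling
distributions under normality — means `N(μ, σ²/n)` and SDs via
`σ·sqrt(χ²(n−1)/(n−1))`. Sampling the SDs (rather than fixing them at σ)
gives realistic variation in se(g). Missing cells are knocked out
independently at the configured rate. Defaults: baseline mean 50, SD 10,
arms of 20–60, no missingness; all reproducible from the seed.

`gen_paper_like` emulates the scale and shape of the curated OSA dataset:
89 studies and 284 indicators whose coverage deciles realize the published
counts (251, 20, 7, 2, 0, 1, 2, 1, 0, 0) exactly — presence counts are drawn
per decile and sampled as exact m-of-89 subsets, so "one indicator near 0.75
coverage" and "33 retained at ICRT = 0.1" hold by construction. Head
indicators carry plausible true effects (severity index δ = −0.9 with
τ = 0.25, REM share +0.45, total sleep time 0, …); the 271-indicator tail is
null with τ = 0.1; missingness 3%. These are the generator's fixed study
conditions, chosen once as a realistic emulation of treatment-effect OSA
trials.

What the generator does **not** emulate: correlated indicator co-reporting
(indicator fashions over time or by lab), publication bias, non-normal
outcome distributions, truly paired within-subject correlation, and
heterogeneity linked to study metadata (design, region, intervention).
Passing tests therefore demonstrate correctness of the screening arithmetic
and calibration of the pooled inference under the stated sampling model —
not robustness to those real-data features.

## Problem sizes and numerical checks

The test suite exercises profile construction against an exhaustive
exact-rational oracle on 200 random fixtures of ≤ 8 studies × ≤ 10
indicators (all 100 grid combinations enumerated with `fractions.Fraction`),
and calibration over 2000 seeded replicates of a 12-study meta-analysis with
40–60 subjects per arm: 95%-CI coverage of a true δ = −0.8, power for the
decrease call, and type-I error under the null. The paper-scale synthetic
runs (89 × 284) complete in a few seconds. Hedges' g is cross-checked
against an independent implementation (statsmodels) — point estimates agree
to machine precision; the variance conventions differ analytically by
`g²/2·(1/(n−3.94) − 1/n)`, which the test asserts exactly rather than hiding
behind a loose tolerance.

## Known limitations

- The profile-selection collapse rule is the package's declared
  interpretation; it is validated against the degenerate forced case and an
  exhaustive oracle, but the reference analysis's exact 22-profile selection
  can only be confirmed against the separately distributed curated dataset.
- No small-study/publication-bias statistics beyond funnel data (no Egger,
  trim-and-fill), no meta-regression, no sensitivity or subgroup analysis.
- Per-test α with no multiplicity control: significance counts across
  profiles are descriptive, not family-wise error-controlled.
- Two-group and paired designs are pooled on the same independent-groups
  contrast; for paired designs this understates precision.
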