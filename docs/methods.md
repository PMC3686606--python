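# Methods

This note documents the statistical model behind `bicarotid`, the choices
made where the methodology left room, and what the synthetic-data results
do and do not establish.

## Geometry classification and the phenotype taxonomy

Each common carotid artery contributes two continuous measures: far-wall
intima-media thickness (IMT, mm) and external interadventitial diameter
(mm). A measurement is *large* when it is at or above the sex- and
side-specific median — the inclusive rule matters only when medians are
supplied externally (with data-derived midpoint medians of continuous
measurements, exact ties cannot occur; with published three-decimal
medians they can, and ties count as large). Medians are recomputed from
the analysis sample by default; supplied values are accepted through the
`MedianTable` type and the CLI's `--medians` option.

The four per-side patterns (both large / IMT only / diameter only /
neither) form 16 ordered right×left pairs, collapsed under right–left
symmetry into ten phenotypes ordered roughly by severity. The six combined
phenotypes are fixed unions of ids:

| name | ids | reading |
|---|---|---|
| IMT_BILAT | 1,2,5 | IMT large on both sides, diameter free |
| DIA_BILAT | 1,3,8 | diameter large on both sides, IMT free |
| ANY_BILAT | 1,2,3,5,8 | any parameter bilaterally large |
| SAME_SIDE_BOTH | 1,2,3,4 | both parameters large on at least one side |
| ANY_IMT | 1–7 | IMT large anywhere |
| ANY_DIA | 1,2,3,4,6,8,9 | diameter large anywhere |

Counts over the ten ids partition any cohort, and every combined row is an
exact sum over its constituents — both are enforced by tests.

## Concordance statistics

Overall right–left agreement is Cohen's unweighted κ on the 4×4
cross-classification, with the Fleiss–Cohen–Everitt large-sample variance
for the 95% CI. Per-category agreement is the *specific positive
agreement* `2·n_cc/(row_c + col_c)`: of all right- or left-side
classifications into category c, the proportion whose opposite side
agrees. This statistic was chosen because it is the standard per-category
companion to κ; its CI is a seeded multinomial bootstrap over subjects
(2000 resamples by default, percentile method), since no analytic form is
canonical for it. Both choices are flagged here as package assumptions:
published per-category agreement figures of this kind rarely state their
formula, and alternative definitions (e.g. conditional row agreement)
differ in the third decimal at cohort scale but are not identical.

## Diagnostic accuracy

For a positivity set S of phenotype ids, the 2×2 table crosses membership
in S with incident stroke. Likelihood ratios use the delta method on the
log of a ratio of binomial proportions (the Simel log method):

    SE(ln LR+) = sqrt((1 − sens)/tp + spec/fp)
    SE(ln LR−) = sqrt(sens/fn + (1 − spec)/tn)

with 95% bounds `LR·exp(±1.96·SE)`. This formula was validated by exact
reproduction of an independently published interval (+LR 3.10, CI
2.56–3.76, from tp=42, fp=810, fn=24, tn=3138). If any cell is zero, 0.5
is added to all four cells and the result flagged (`corrected=True`); the
identities `LR⁺·(1−spec) = sens` and `LR⁻·spec = 1−sens` then hold on the
corrected cells, and hold exactly on raw cells otherwise.

Relative risk is the direct ratio of cumulative incidences with the usual
log-delta CI, `SE(ln RR) = sqrt(1/e₁ − 1/n₁ + 1/e₀ − 1/n₀)`. Person-time
or model-based alternatives would give different values for the same
counts; only the direct-ratio definition is implemented. Display rounding
is two decimals for proportions and ratios, one for percents; full
precision is kept internally.

## Cox proportional-hazards estimation

The fitter maximizes the log partial likelihood by Newton–Raphson with
step-halving, starting from β = 0. Risk-set sums S₀, S₁, S₂ are suffix
cumulative sums over time-sorted subjects, so one evaluation is O(np²).
Convergence requires max|gradient| < 1e−8 or relative log-likelihood
change < 1e−10 (the returned gradient norm is asserted < 1e−6 in tests).
Standard errors come from the inverse observed information at the
solution.

Numerical safeguards:

- the linear predictor is centred by its maximum before exponentiation
  (the partial likelihood is shift-invariant), preventing overflow;
- a coefficient exceeding 20 in absolute value raises `SeparationError` —
  a monotone likelihood has no finite maximizer, and reporting a
  pseudo-converged estimate would be misleading;
- a rank-deficient design raises an error naming a collinear term.

**Ties.** Breslow is the default (the convention of the era's mainstream
survival software for this kind of analysis); Efron is available via
`ties="efron"`. The two agree exactly on tie-free data (tested), and both
agree with lifelines to ~1e−6 — lifelines serves only as an independent
cross-check, never as the implementation.

**Covariate retention.** `select_covariates` implements the classical
epidemiological procedure: geometry indicators and base adjustment terms
(age, race, height) are forced in; candidates are backward-eliminated,
dropping the highest p ≥ α (α = 0.05, ties in p broken by term name for
determinism) unless removal shifts any geometry coefficient by more than
δ = 10%. The shift is measured relative on the coefficient (log-hazard)
scale by default, because that is the scale on which the model is linear;
`change_scale="hr"` switches to the hazard-ratio scale since published
descriptions of the 10% rule rarely say which was used. Coefficients
within 1e−6 of zero fall back to an absolute shift. Every decision is
logged in an ordered audit trail. Polynomial terms (e.g. a squared
triglyceride term) enter as pre-computed design columns via
`geometry_design(..., extra_terms=...)`.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
exercised:

- **Measures.** The four log-measurements are jointly Gaussian with a
  separable correlation `Side ⊗ Param`, `Side = [[1, ρ_b], [ρ_b, 1]]`,
  `Param = [[1, ρ_w], [ρ_w, 1]]`; the cross term (right IMT with left
  diameter) is ρ_b·ρ_w. The Kronecker product of positive-definite
  matrices is positive definite, so any ρ_w, ρ_b ∈ (−1, 1) is valid.
  Measures are the exponentials (log-normal: positive and right-skewed,
  as arterial dimensions are), with sex- and side-specific log-medians
  defaulting to the published medians (men 0.663/0.676 mm IMT,
  8.092/7.997 mm diameter R/L; women 0.609/0.603 and 7.303/7.199) and
  σ_log = 0.15. Because the median split only sees ranks, the marginal
  shape is irrelevant to prevalences; the Gaussian copula governs them
  exactly via the orthant formula `P(both large) = 1/4 + arcsin(ρ_w)/(2π)`.
- **Defaults.** ρ_w = `calibrate_within_correlation(0.32)` ≈ 0.4258 gives
  the observed 32/18/18/32% per-side pattern split. ρ_b = 0.35 is *not*
  identified from published data (only categorical agreement is
  published); it is set so the "neither/neither" specific agreement lands
  in the mid-40s%, near the published 46–48%. Under these defaults the
  phenotype-1 prevalence (~15%) runs below the observed ~21% — matching
  it would require ρ_b ≈ 0.6, which overshoots the agreement column; the
  tension is inherent in calibrating one parameter to two targets and ρ_b
  is exposed as config for users who prefer the other target.
- **Outcomes.** Event times are exponential with rate
  `h₀·exp(log HR[phenotype])` — the simplest hazard compatible with the
  proportional-hazards analysis; a Weibull shape would slot into the same
  config surface. Defaults: h₀ = 0.0006/yr, chosen so the reference
  phenotype's ~11-year cumulative incidence is ~0.7% and the overall
  incidence ~2.4%, as in the published count table; the hazard-ratio
  gradient (9, 4, 4, 1, 4, 1.5, 1.5, 2.5, 1.5, 1 for ids 1–10) mirrors
  the published incidence gradient. Censoring is Uniform(10, 12) years;
  `event = 1` iff the event time precedes the censoring time.
- **Covariates.** Age ~ Uniform(45, 64), race black with p = 0.27, height
  normal per sex (176.2 ± 6.4 / 162.4 ± 5.8 cm), drawn independently of
  the measures by default; prevalent stroke with p = 0.022 for exercising
  the exclusion flow.
- **Reproducibility.** All draws come from one counter-based (Philox)
  stream keyed by the config seed; identical seeds give bit-identical
  cohorts and byte-identical pipeline reports.

What the generator deliberately does **not** emulate: sex-specific
hazards, covariate–phenotype confounding (available via config but off by
default), the full 19-variable risk-factor panel, measurement error and
reader variability, plaque-level structure, and the sampling design of a
multi-site cohort. Passing tests therefore demonstrate the correctness of
the *statistical machinery* under the assumed data-generating process,
not the clinical reproducibility of the original effect sizes on real
subjects.

## Validation strategy and problem sizes

The published side-specific hazard ratios cannot be recomputed without
restricted subject-level data, so the survival stack is validated by:

- brute-force agreement: on small tie-free instances (6–10 subjects) the
  fitter matches an independent 1-D grid/bounded maximization of the
  hand-written Breslow partial likelihood to 1e−6;
- parameter recovery: 200 simulated cohorts of 3300 subjects with a true
  both-large hazard ratio of 3.7 (baseline hazard 0.0016/yr, giving
  ~100–120 events per cohort); the mean estimated log-HR falls within 3
  Monte-Carlo SEs of ln 3.7 and 95% Wald coverage within its binomial
  band. A small upward finite-sample bias of the log-HR MLE (~2–3% at
  this event count) is visible and expected;
- cross-checks of κ and the likelihood-ratio identities against hand
  formulas and randomized tables.

Simulation sizes (200 replicates; 80 000 draws for calibration checks;
7437 subjects for cohort-scale reports) were chosen so Monte-Carlo error
is well below the tolerances being asserted while the full suite runs in
well under a minute.

## Known limitations

- Cut-points are medians by construction; no optimized thresholds, ROC
  analysis or predictive values.
- No time-varying covariates, stratified baselines, delayed entry,
  competing risks or proportionality diagnostics in the Cox fitter.
- The specific-agreement definition and its bootstrap CI are package
  choices (see above) and may not match any particular published variant.
- Relative risk is the direct incidence ratio only.
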