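# Methods

This note documents the statistical procedures, the defaults and their
rationale, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would want spelled out. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Scoring

Raw scores are per-scale means of the answered items; a scale mean is defined
when at least half the items are answered (the standard half-rule; no other
imputation is performed). The 0–100 transformation is

- functioning: `100 · (1 − (raw − 1) / range)`
- symptom: `100 · (raw − 1) / range`, then reversed to `100 − value`
- global QoL: `100 · (raw − 1) / 6` (already oriented best-high)

so after the symptom reversal every scale reads 0 = worst, 100 = best.
The reversal is applied at scoring time, not report time, so all change
scores and MIDs share one sign convention: deterioration MIDs are negative.
Version 2 differs from version 3 only in items 1–5 (yes/no coded 1/2,
`item_range = 1`); versions may be pooled across trials, and the
trial-heterogeneity test below is the guard against pooling artefacts.
The global QoL scale is treated as already best-high and is not reversed.
The financial-difficulties scale is scored but excluded from analysis.

## Latent correlations and anchor retention

Polyserial (continuous × ordinal) and polychoric (ordinal × ordinal)
correlations use two-step maximum likelihood: thresholds fixed at
`Φ⁻¹(cumulative marginal proportions)` (zero-count categories collapse into
their neighbours), then a bounded 1-D search for ρ.

Numerical choices: ρ constrained to (−0.999, 0.999); convergence tolerance
1e−6 on ρ (`scipy.optimize.minimize_scalar`, bounded); cell/observation
probabilities floored at 1e−300 before logging; bivariate normal rectangle
probabilities by second differences of the joint CDF with infinite bounds
clipped at ±8.5. Estimators require ≥ 30 complete paired observations and a
non-degenerate ordinal; anything less is reported as a skipped pair with its
reason, never silently dropped.

Method auto-selection: polyserial when the scale has more than 7 distinct
observed values, polychoric otherwise (single-item scales have ≤ 4 levels).
Screening pools all timepoints and ignores within-patient clustering — it is
a filter, not an inference, and no confidence intervals are attached.
Retention requires cross-sectional |ρ̂| ≥ 0.3; change-score correlations are
computed (ordinal variable = raw anchor grade change) and reported but do not
gate retention, since a pair can be strongly cross-sectionally coupled yet
weakly coupled in changes.

## Change records and clinical change groups

The analysis unit is the (patient, ordered timepoint pair) record, default
pairing = all pairs i < j of a patient's complete assessments
(`consecutive` offered as a sensitivity switch). Intermittent missing
assessments are handled by treating each pair independently: a pair enters
iff both ends carry a score and an anchor grade; skipped pairs are counted.
No cap is placed on the time elapsed between paired assessments.

Anchor changes are sign-adjusted by the anchor's `worse_direction` so +1
always means health improved one category. Groups: improved (+1), stable (0),
deteriorated (−1), excluded (|change| ≥ 2, i.e. more than minimal change).
Excluded records are carried for audit but barred from every estimate,
including the effect-size denominator.

## MID estimation

- **Within-group:** mean change score in the target CCG; standard error by
  patient-level cluster-robust variance of the mean.
- **Between-group:** GEE (Gaussian family) of change on the target-vs-stable
  indicator, patient-level clusters, exchangeable working correlation by
  default with robust sandwich SEs. Independence is available by
  configuration; with independence and one record per patient the coefficient
  reduces exactly to the two-sample mean difference (a tested identity). The
  working correlation affects efficiency only — robust SEs keep inference
  structure-insensitive. Models are fitted separately per direction
  (improved-vs-stable, deteriorated-vs-stable) and per (scale, anchor) pair;
  when several anchors survive for one scale, all pairs are estimated and the
  summary table reports the anchor with the strongest cross-sectional
  correlation.
- **Effect size:** mean change in the target CCG divided by the SD of all
  (non-excluded) change scores of that (scale, anchor) pair. Retention band
  0.2 ≤ |ES| < 0.8: the lower bound is inclusive (only effects below the
  small-effect floor are dismissed), the upper bound exclusive (a large
  effect is more than minimal change). Between-group estimates inherit the
  within-group gate so a (scale, direction) is retained or withheld as a
  unit. Every filter decision is written to the run log.
- **Trial heterogeneity:** the between-group model is extended with trial
  main effects and indicator × trial interactions; the robust Wald p-value of
  the interaction block is flagged at the 1% level (stringent because the
  test is repeated across many scales; no further multiplicity adjustment is
  layered on).

## Distribution-based estimates

0.3 SD, 0.5 SD and SEM are computed on each patient's first assessment (t1).
SEM = SD·√(1 − r). The reliability r is Cronbach's α at t1 when ≥ 2 items
with responses are available; otherwise a t1→t2 Pearson correlation among
patients whose anchor is stable over that pair (a test-retest stand-in,
clipped into [0, 1]), with the source recorded per scale. These values are
comparators only and never gate anchor-based retention.

## Synthetic generator

The generative model is change-score based so the true within-group MID is a
direct configuration parameter: anchors evolve by a per-step transition
matrix; each ±1 transition shifts the score level by the configured true MID
for that direction; each assessment adds independent measurement noise of SD
`change_noise_sd / √2`, so every pairwise change score carries noise SD
`change_noise_sd` regardless of lag and cross-sectional SDs do not grow with
time (a pure random walk would inflate them and attenuate pooled
correlations). Monotone dropout censors patients geometrically.

Because MID-driven shifts at later timepoints add score–anchor coupling on
top of the baseline latent, the generator *calibrates* its baseline coupling
coefficient on the realized draws — solving
`corr(S, E[U | grade]) = ρ_target · sd(E[U | grade])` (the closed-form
polyserial identity) by bounded root finding — so the pooled cross-sectional
correlation matches the configured target by construction. Infeasible
configurations (score range entirely outside 0–100, noise too large for the
requested correlation, unreachable targets) raise errors rather than warp.

Defaults (the shipped scenario): two trials of 500 patients, four
assessments, baseline scores 65 ± 16, true MIDs +5 / −10, change noise SD 8,
anchors PS and CTCAE diarrhoea with majority-stable transitions (diagonal
0.78, ±1 moves 0.095, ±2 moves 0.015, boundary mass folded onto the
diagonal) and initial distributions concentrated in the low grades. The
baseline mean is deliberately mid-range so floor/ceiling truncation does not
distort the configured MID estimands; seven scales carry couplings of
0.33–0.50 in magnitude and two (EF, NV) sit below the 0.3 retention
threshold so the no-anchor reporting route is exercised. With truth −10
against noise SD 8 the deterioration effect size is ≈ 1.1, so the default
report correctly withholds deterioration MIDs as `no MID` (|ES| ≥ 0.8) — an
intended property of this stated world, not a failure mode.

Item emission is optional (off by default): multi-item scales are
inverse-scored into integer responses whose re-scored value reproduces the
stored score within one lattice step, which exercises the scoring and
Cronbach-α machinery but quantises scores onto the achievable lattice
(adding up to ~5 points of SD for 2-item scales). Single-item scales never
emit items and remain continuous constructs.

What a green test does **not** establish: the generator draws anchors and
scores from a tidy Markov/Gaussian world — it does not emulate informative
(MNAR) dropout, ceiling-concentrated baselines of highly functional
populations, item-level missingness patterns, the 4-level granularity of
real single-item scales, or calendar-time spacing of assessments. Recovery
on this world validates the estimation machinery, not the clinical
generalisability of any particular MID value.

## Known limitations

- Ordinal anchor grades are treated as interval steps (one category = one
  "minimal" unit), as in the underlying methodology.
- Screening correlations ignore within-patient clustering.
- Group-level MIDs only; no individual-patient responder thresholds, no
  IRT-based scoring, no Bayesian estimation.
- The stability-proxy reliability conflates test-retest error with real
  residual change in anchor-stable patients and can overstate SEM when
  anchors are coarse.
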