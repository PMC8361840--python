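# Methods

## The value model

The quantitative core of an EVIDEM appraisal is a linear additive value
function over the n criteria of the core model:

    V = Σₓ Vₓ = Σₓ (Wₓ · Sₓ)

* **Weights.** Each panelist rates each criterion's importance on 1–5
  (5 = most important); fractional values are accepted because committees
  sometimes rescale individual ratings before pooling. The panel mean weight
  per criterion is normalized to unit sum over the included criterion set:
  Wₓ = w̄ₓ / Σ w̄. This is the "transformed to a 0–1 scale" step: it makes V
  a convex combination of standardized scores, not a post-hoc min–max
  rescaling across interventions (which would force the best and worst drug
  to exactly 1 and 0 and destroy the interpretation of V as an absolute
  value level).
* **Scores.** Absolute criteria are rated 0–5 on the intervention's own
  merits; relative criteria are rated −5..+5 against a comparator. Both are
  standardized by Sₓ = s̄ₓ / 5, mapping absolute criteria into [0, 1] and
  relative criteria into [−1, 1]. Dividing by 5 rather than min–max mapping
  −5..5 onto 0..1 deliberately preserves the sign of comparative harms: a
  drug priced above its comparator *subtracts* value. Consequently
  V ∈ [−1, 1], and V ∈ [0, 1] whenever no criterion is scored negative.
* **Aggregation level.** V is computed from panel means (aggregate-then-
  combine). Averaging per-panelist V values instead gives the same result
  only when every panelist answered every cell; with raw matrices supplied
  the per-panelist path is available by fitting on the raw `PanelMatrices`.
  This is a documented limitation, not a configurable mode.

Sample statistics use the n−1 (sample SD) convention throughout, which is
what printed committee tables such as "4.33 ± 0.52 over six panelists"
reproduce; a single respondent yields SD 0.

## Missing-criterion policy

Committees sometimes weight a criterion and then find no evidence to score
it. Which arithmetic follows is genuinely open, so both natural readings are
implemented and exposed:

* `retain_weights` (default) — unscored criteria keep their mean weight in
  the normalization denominator and contribute Sₓ = 0. The committee's
  stated importance structure is preserved; absent evidence is valued as
  neutral. On the built-in worked example this is also the reading that
  lands closest to the committee's published totals, which is why it is the
  default.
* `renormalize_excluding` — unscored/unweighted criteria are dropped before
  normalization, so the remaining weights are rescaled to unit sum.

Both policies apply one denominator to all interventions, so the value
*ordering* is provably identical under either; only the level of V shifts
(on the worked example, ~0.44 vs ~0.48 for the top drug). A criterion counts
as *scored* only if it has a pooled score for **every** intervention; a
partially scored criterion cannot support a fair comparison and is treated
as unscored.

The worked example's published totals (0.45 … 0.40) are reproduced to within
0.012 under `retain_weights` (0.44, 0.43, 0.42, 0.41, 0.39 at two decimals)
and the published ordering is reproduced exactly under both policies. The
residual offset is consistent with an undocumented detail of the original
spreadsheet normalization; no ad-hoc rescaling is applied to close it.

## Ranking

Interventions are ordered by descending V. Exact ties share the minimum
(competition) rank and are listed alphabetically within the tie; the result
is invariant to input order. Reported values are rounded half-up to two
decimals for display; full precision is kept internally.

## Rank-stability simulation

The point estimate ignores the dispersion the panel reported. The simulator
draws, per Monte-Carlo replicate, every weight from a normal centred on its
mean and truncated to [1, 5], and every score from a normal truncated to its
criterion's scale, then recomputes the normalization, V and the ranking, and
tabulates rank frequencies — a rank-acceptability table in the spirit of
stochastic multicriteria acceptability analysis, but anchored to the
elicited dispersion instead of an uninformed weight space.

Choices that matter:

* **Sampling scale.** Default is the standard error of the panel mean,
  SD/√n_panelists — the decision-relevant uncertainty is in where the panel
  mean truly lies. `uncertainty="sd"` samples at the raw SD instead, probing
  panel heterogeneity (it scrambles the ranking much more).
* **Independence.** Draws are independent across criteria and between
  weights and scores; no covariance is elicited, so none is imposed.
* **Ties.** Within a draw, ranks are ordinal with alphabetical tie-break, so
  every draw yields a full permutation and the rank-probability table is
  doubly stochastic (rows and columns sum to 1). With all SDs at 0 the table
  degenerates to the permutation matrix of the deterministic ranking.
* **Determinism.** One documented generator (`numpy.random.default_rng`);
  identical seeds give bit-identical tables. 10,000 draws run in about a
  second; the suite's convergence check uses SD = 1e−6 at 2,000 draws.

## Synthetic committees

Raw panelist matrices are rarely published; appraisals print only mean ± SD.
The generator emulates the committee process behind such tables: n panelists
(reference committee size 6 — two doctors, a nurse, a pharmacist, a health
economist, a decision-maker) produce integer scores on the criterion scales
and fractional weights in [1, 5], targeting configurable per-column
(mean, SD).

* Integer columns draw from a truncated normal, round to scale points, then
  a repair pass nudges random entries ±1 until the column sum equals a
  randomized integer target with expectation n × mean. Mean targets are thus
  hit to the nearest feasible integer sum per panel and are *unbiased across
  replicate panels*, even for targets with no exact integer solution at
  n = 6 (e.g. 4.67). SD targets are soft: matched in distribution, not per
  panel.
* Fractional weight columns draw from the truncated normal and are recentred
  onto the target mean (recentre/clip iterated), leaving only a negligible
  clipping bias for targets well inside [1, 5].
* A zero-SD target means a unanimous committee: a constant column at the
  target mean, rounded to the nearest scale point for integer columns.
* Infeasible targets error early, naming the criterion: means outside the
  scale, SDs above the bounded-scale maximum (hi−lo)/2·√(n/(n−1)), or any
  positive SD with a single panelist.

What the generator does **not** model: panelist-role effects, inter-criterion
correlation within a panelist, and systematic response styles (e.g.
end-aversion). Passing the parameter-recovery tests therefore shows the
pipeline is unbiased under independent truncated-normal elicitation noise;
it does not validate the model against the behaviour of a real committee.

## Problem sizes and tolerances used by the test suite

Chosen as the package's own verification budget: oracle equivalence on 1,000
random aggregated panels at 1e−12 absolute; parameter recovery over 200
replicate six-member panels at ±0.15 on every grand mean (the Monte-Carlo
scale of SD/√(6·200) with headroom); rank-stability determinism and
degeneracy at 10,000 draws; pipeline closure over 100 random profiles.
Normalized-weight sums are asserted at 1e−9; value decompositions at 1e−9.

## Known limitations

* The contextual tool is carried as qualitative annotations only; it never
  enters V (by design of the framework).
* No imputation: missing panelist responses stay missing and flow into the
  missing-criterion policy rather than being filled.
* Weight elicitation is direct 1–5 rating only — no AHP, swing weighting or
  discrete-choice methods.
* V values computed from panel means mask between-panelist disagreement; the
  rank-stability table is the provided remedy, not a hierarchical model.
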