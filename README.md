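# evidem-mcda

Additive multi-criteria decision analysis (MCDA) for hospital formulary
appraisal, following the EVIDEM framework (Evidence and Value: Impact on
Decision Making).

Hospital pharmacy committees must choose between near-equivalent drugs under
time pressure. An EVIDEM-style appraisal makes that choice transparent: a
panel first rates the **importance** of each criterion in a fixed 13-criterion
quantitative core model (weights, 1–5), then rates each candidate drug's
**performance** on every criterion (scores, 0–5 for absolute criteria and
−5..+5 for criteria judged against a comparator). The package turns those
elicitations into a single value estimate per drug:

```
V = Σₓ Vₓ = Σₓ (Wₓ · Sₓ)
```

where `Wₓ` is the normalized weight (mean panel weight divided by the sum of
mean weights, so Σ Wₓ = 1) and `Sₓ` is the standardized score (mean panel
score divided by 5, preserving the sign of worse-than-comparator
performance). V is dimensionless and lies in [−1, 1].

The package provides:

* the EVIDEM 13-criterion core model and 7-criterion qualitative contextual
  tool as validated, serializable criterion sets (`evidem_mcda.registry`);
* panelist-level weight/score matrices with strict range validation and
  mean ± SD aggregation (`evidem_mcda.panel`);
* the additive valuation with two explicit policies for criteria a committee
  weighted but never scored, as an sklearn-style estimator
  (`evidem_mcda.valuation.EvidemValuator`);
* Monte-Carlo rank-stability analysis that propagates the panel's reported
  SDs through the value model (`evidem_mcda.stability`);
* a synthetic-committee generator targeting configurable mean ± SD
  aggregates (`evidem_mcda.synthetic`);
* a CLI (`evidem value|rank|simulate|generate|report`) and a JSON report
  schema (`evidem_mcda.report`).

A complete worked example is built in: a six-member committee's appraisal of
the five DPP-4 inhibitors marketed in China (Saxagliptin, Alogliptin,
Sitagliptin, Linagliptin, Vildagliptin), including the committee's
missing-data quirks (preventive benefit never weighted or scored; other
medical costs weighted but unscored).

## Worked example

```python
from evidem_mcda import load_dpp4_fixture, EvidemValuator

model, agg = load_dpp4_fixture()
valuator = EvidemValuator(policy="retain_weights").fit(agg)
print(valuator.value_table())
```

```
 rank intervention        V
    1  Sitagliptin 0.437761
    2  Linagliptin 0.429510
    3 Vildagliptin 0.417345
    4   Alogliptin 0.410107
    5  Saxagliptin 0.392949
```

Rounded to the two decimals of a committee report, the values are 0.44, 0.43,
0.42, 0.41 and 0.39: the five drugs are close in overall value, Sitagliptin
leads and Saxagliptin trails. The per-criterion decomposition shows where a
value comes from — `valuator.decomposition("Sitagliptin")` reveals that
comparative effectiveness (Vₓ = 0.083) and population size (0.074) carry the
value, while patient-reported outcomes, drug cost and non-medical costs
contribute negatively (the drug is priced above its comparator).

How stable is the purchasing order, given the committee's dispersion? The
rank-stability simulation resamples weights and scores from truncated
normals at the standard error of each panel mean and recomputes the ranking:

```python
from evidem_mcda import simulate_ranks
result = simulate_ranks(agg, n_draws=10_000, seed=42)
print(result.rank_probability.round(3))
```

```
                  1      2      3      4      5
Saxagliptin   0.023  0.050  0.122  0.231  0.573
Alogliptin    0.080  0.145  0.232  0.322  0.221
Sitagliptin   0.483  0.284  0.149  0.067  0.017
Linagliptin   0.285  0.308  0.221  0.140  0.046
Vildagliptin  0.129  0.213  0.275  0.240  0.142
```

Sitagliptin is the most probable first choice (P ≈ 0.48) but the order is far
from certain — useful context for a committee deciding between similar drugs.

The same pipeline runs from the shell:

```sh
python - <<'PY'
from evidem_mcda import load_dpp4_fixture
load_dpp4_fixture()[1].to_json("dpp4.json")
PY
evidem rank --panel dpp4.json
evidem simulate --panel dpp4.json --draws 10000 --seed 42
```

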