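# mcdakit

Multi-criteria decision analysis (MCDA) for health-intervention coverage
decisions.

Appraisal committees of health plans and HTA bodies must weigh evidence
quality, disease burden, intervention performance and economics at once.
`mcdakit` implements the linear additive MCDA value model used for such
appraisals, together with the surrounding workflow: a configurable
decision-criteria matrix with panel-response validation, descriptive survey
tallies, budget-impact arithmetic, report rendering, and a synthetic
committee generator that reconstructs member-level integer responses from
published summary statistics so the whole pipeline is testable when raw
panel data are unavailable.

## The model

Each committee member *m* assigns every active criterion *c* an integer
importance weight `w_m(c) ∈ {1..5}` and an integer intervention score
`s_m(c) ∈ {0..3}`. Weights are normalized per member to sum to 1, scores
standardized by the scale maximum, and the member's value estimate is

```
V_m = Σ_c  [ w_m(c) / Σ_k w_m(k) ] · [ s_m(c) / 3 ]       ∈ [0, 1]
```

Panel results are the mean, sample SD (n − 1), minimum and maximum of the
`V_m`, plus a per-criterion decomposition: the mean value contribution of
each criterion and its integer-percent share of the panel mean. The model
is additive and non-interacting by design; qualitative *contextual*
criteria (precedent-setting, provider relationships, …) are recorded as
directional impacts and never enter the arithmetic.

## Worked example

```python
import pandas as pd
from mcdakit import MCDAValueModel

weights = pd.DataFrame({"efficacy": [4, 5, 3], "safety": [4, 3, 3], "budget": [2, 5, 4]},
                       index=["m1", "m2", "m3"])
scores = pd.DataFrame({"efficacy": [3, 2, 2], "safety": [0, 1, 1], "budget": [3, 1, 0]},
                      index=["m1", "m2", "m3"])

m = MCDAValueModel().fit(weights, scores)
print(m.member_values_.round(4).to_dict())
print(round(m.mean_, 4), round(m.sd_, 4))
print(m.share_percent_.to_dict())
```

prints

```
{'m1': 0.6, 'm2': 0.4615, 'm3': 0.3}
0.4538 0.1501
{'efficacy': 63, 'safety': 13, 'budget': 24}
```

Member m1's estimate is 0.6: with normalized weights (0.4, 0.4, 0.2) and
standardized scores (1, 0, 1), the intervention realizes 60% of the value
it could have delivered for that member. The panel mean is 45% (SD 15
points), and efficacy drives 63% of the panel's mean value.

The same pipeline is available from the shell:

```sh
mcdakit synth --seed 1 --out weights.csv scores.csv   # synthetic 9×14 committee
mcdakit appraise --weights weights.csv --scores scores.csv --out results/
mcdakit budget --price-new 180.00 --price-old 103.10 --n 1000
mcdakit tally --responses survey.csv --categories always,sometimes,never
mcdakit report --weights weights.csv --scores scores.csv --out report.md
```

`mcdakit budget` above prints an incremental cost of 76.90 per patient
screened and a projected budget impact of 76,900 per 1,000 women per year —
the worked example of the bundled screening-test appraisal.

## Synthetic committees from printed statistics

`mcdakit.synthetic` solves the inverse problem of descriptive reporting:
given a printed per-criterion mean and sample SD (1 dp) over n ≤ 12
members, `reconstruct_vector` exhaustively enumerates all integer
multisets on the scale and returns one whose rounded moments match — or a
proof of infeasibility with the nearest achievable pairs. (One published
score target, mean 2.5 with SD 0.3 over 9 members on 0–3, is provably
unattainable by any integer vector; the package reports this rather than
forcing a fit.) `sample_panel` instead draws seeded random panels from
moment-matched discrete distributions, for property testing at scale.

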