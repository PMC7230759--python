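# nutriprofile

Front-of-package (FOP) nutrient profiling of prepacked foods: classify
products under ten labelling/profiling schemes, harmonise every scheme's
output to a binary **"healthier"** verdict, and compare the schemes with
per-category proportions, sales-weighted proportions, Cohen's kappa and
symbol-vs-rating conflict scenarios.

Built for public-health nutrition researchers and food-policy analysts who
need to ask: *would two labelling schemes on the same shelf give consumers
conflicting signals?*

## The schemes

| Scheme | Type | Healthier means |
| --- | --- | --- |
| Nutri-Score (2017) | rating, N − P points | grade A or B |
| Health Star Rating (2016) | rating, baseline − modifying points | ≥ 3.5 stars |
| UK FSA traffic light (per 100 g) | rating, colour bands | no red light |
| Protective Food symbol | health symbol | allowed to carry symbol |
| Keyhole, Choices, Finnish Heart | health symbols | allowed to carry symbol |
| Ofcom NPM, WHO-Europe | marketing-to-children profiles | permitted |
| FSANZ NPSC | health-claim gate | permitted to carry claims |

The point models share one skeleton: negative points from energy, saturated
fat, total sugars and sodium, minus positive points from
fruit/vegetable/nut content, fibre and protein, with a protein-suppression
rule for energy-dense products. E.g. for Nutri-Score,

```
score = (energy + sat_fat + sugars + sodium points) − (FVN + fibre + protein points)
A ≤ −1 < B ≤ 2 < C ≤ 10 < D ≤ 18 < E
```

Every numeric table and limit is versioned YAML config under
`src/nutriprofile/data/`, pinned by checksum in the tests — the code fixes
only the scoring skeletons. Agreement between two schemes' verdicts is
Cohen's κ = (p_o − p_e)/(1 − p_e); when both verdicts are constant the
statistic is 0/0 and is reported as 0 with a `degenerate` flag.

## Worked example

```python
from nutriprofile import NutrientPanel, nutriscore, traffic_light, protective_food

yoghurt = NutrientPanel(energy=260, total_fat=3.5, sat_fat=2.4,
                        total_sugars=4.7, salt=0.1, protein=4.0)

bd = nutriscore(yoghurt, "general_food")
print(bd.raw, bd.component_points)
# B (+1) {'energy': 0, 'total_sugars': 1, 'sodium': 0, 'sat_fat': 2,
#         'fvn': 0, 'fibre': 0, 'protein': 2}

tl = traffic_light(yoghurt)
print(tl.colours, tl.healthier)
# {'total_fat': 'amber', 'sat_fat': 'amber', 'total_sugars': 'green',
#  'salt': 'green'} True

pf = protective_food(yoghurt, "yoghurt_plain")
print(pf.eligible, pf.failed)
# False ['total_fat < 3', 'sat_fat < 1.5']
```

Read it as: this plain yoghurt collects 3 negative points (2 for saturated
fat, 1 for sugars) against 2 protein points, final score +1 → Nutri-Score
**B**, so the rating scheme calls it healthier; the traffic light shows no
red, so that scheme agrees; but the Protective Food symbol's strict dairy
limits (< 3 g fat, < 1.5 g saturated fat) refuse it the symbol. Same
yoghurt, three different signals — exactly the kind of (dis)agreement the
comparison pipeline quantifies.

## Command line

```sh
nutriprofile simulate --seed 7 --out supply.csv          # synthetic market (800 products)
nutriprofile validate --input supply.csv                 # row-level validation report
nutriprofile profile  --input supply.csv --out cls.csv   # products x models verdicts
nutriprofile compare  --input supply.csv --out reports/  # proportions, kappa, scenarios
```

`compare` writes `proportions.csv` (per category and model, with
sales-weighted shares when sales are present), `kappa.csv` (every model
against Nutri-Score and against the Protective Food symbol, with agreement
band labels), and `summary.json` including the four labelling scenarios for
the configured symbol/rating pair: A (green rating + symbol), B (green
only), C (symbol but non-green — the conflicting case), D (neither).

Because the real survey behind the published comparisons is not deposited,
the `simulate` subcommand generates a seeded synthetic market with the same
category structure (see `docs/methods.md` for what it does and does not
emulate), including heavy-tailed sales that can be biased so market leaders
are systematically less healthy (the breakfast-cereals pattern) or more
healthy (the cheese pattern) than their category average.

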