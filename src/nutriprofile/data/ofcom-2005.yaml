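# Ofcom / UK FSA nutrient profile model (2004/05) used for gating food
# advertising to children.  A-points (energy, sat fat, sugars, sodium, max 10
# each) minus C-points (fvn, fibre, protein, max 5 each); a food is "less
# healthy" at score >= 4 (drinks >= 1).
model: ofcom
version: "2004/05"
categories: [food, drink]
negative:
  energy:
    comparator: gt
    thresholds: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sat_fat:
    comparator: gt
    thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  total_sugars:
    comparator: gt
    thresholds: [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sodium:
    comparator: gt
    thresholds: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
positive:
  fvn:
    comparator: gt
    thresholds: [40, 60, 80]
    points: [1, 2, 5]
  fibre: # AOAC variant shipped as default; NSP selectable
    comparator: gt
    thresholds: [0.9, 1.9, 2.8, 3.7, 4.7]
    points: [1, 2, 3, 4, 5]
  fibre_nsp:
    comparator: gt
    thresholds: [0.7, 1.4, 2.1, 2.8, 3.5]
    points: [1, 2, 3, 4, 5]
  protein:
    comparator: gt
    thresholds: [1.6, 3.2, 4.8, 6.4, 8.0]
    points: [1, 2, 3, 4, 5]
fibre_variant: fibre
protein_suppression:
  negative_min: 11
  fvn_exempt_points: 5
  exempt_categories: []
pass_below: # permitted for marketing to children iff score < cut-off
  food: 4
  drink: 1
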