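# Health Star Rating (Australia/New Zealand, 2016 calculator).
# Baseline points (energy, sat fat, total sugars, sodium) minus modifying
# points (FVNL, fibre, protein), mapped to 0.5-5.0 stars through the
# published per-category score->star breakpoint tables.
# Category codes: food (HSR category 2), dairy_food (2D), oils (3),
# dairy_cheese (3D).  Dairy categories are exempt from the 13-point protein
# suppression rule; oils and cheese use the extended saturated-fat table.
model: hsr
version: "2016"
categories: [food, dairy_food, oils, dairy_cheese]
negative:
  energy:
    comparator: gt
    thresholds: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sat_fat:
    comparator: gt
    thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sat_fat_extended:
    comparator: gt
    thresholds:
      [
        1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
        11.2, 12.5, 13.9, 15.5, 17.3, 19.3, 21.6, 24.1, 26.9, 30,
        33.5, 37.4, 41.7, 46.6, 52, 58, 64.7, 72.3, 80.6, 90,
      ]
    points:
      [
        1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
        11, 12, 13, 14, 15, 16, 17, 18, 19, 20,
        21, 22, 23, 24, 25, 26, 27, 28, 29, 30,
      ]
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
  fibre:
    comparator: gt
    thresholds:
      [0.9, 1.9, 2.8, 3.7, 4.7, 5.4, 6.3, 7.3, 8.4, 9.7, 11.2, 13, 15, 17.3, 20]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
  protein:
    comparator: gt
    thresholds:
      [1.6, 3.2, 4.8, 6.4, 8.0, 9.6, 11.6, 13.9, 16.7, 20, 24, 28.9, 34.7, 41.6, 50]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
extended_sat_fat_categories: [oils, dairy_cheese]
protein_suppression:
  baseline_min: 13
  fvn_exempt_points: 5
  exempt_categories: [dairy_food, dairy_cheese]
star_map: # final score -> stars; first band whose upper bound holds
  food:
    - { max: -11, stars: 5.0 }
    - { max: -7, stars: 4.5 }
    - { max: -2, stars: 4.0 }
    - { max: 2, stars: 3.5 }
    - { max: 6, stars: 3.0 }
    - { max: 10, stars: 2.5 }
    - { max: 15, stars: 2.0 }
    - { max: 20, stars: 1.5 }
    - { max: 25, stars: 1.0 }
    - { max: null, stars: 0.5 }
  dairy_food:
    - { max: -2, stars: 5.0 }
    - { max: 0, stars: 4.5 }
    - { max: 2, stars: 4.0 }
    - { max: 4, stars: 3.5 }
    - { max: 6, stars: 3.0 }
    - { max: 8, stars: 2.5 }
    - { max: 11, stars: 2.0 }
    - { max: 14, stars: 1.5 }
    - { max: 17, stars: 1.0 }
    - { max: null, stars: 0.5 }
  oils:
    - { max: 13, stars: 5.0 }
    - { max: 16, stars: 4.5 }
    - { max: 20, stars: 4.0 }
    - { max: 23, stars: 3.5 }
    - { max: 27, stars: 3.0 }
    - { max: 30, stars: 2.5 }
    - { max: 34, stars: 2.0 }
    - { max: 37, stars: 1.5 }
    - { max: 41, stars: 1.0 }
    - { max: null, stars: 0.5 }
  dairy_cheese:
    - { max: -2, stars: 5.0 }
    - { max: 2, stars: 4.5 }
    - { max: 6, stars: 4.0 }
    - { max: 10, stars: 3.5 }
    - { max: 14, stars: 3.0 }
    - { max: 18, stars: 2.5 }
    - { max: 22, stars: 2.0 }
    - { max: 26, stars: 1.5 }
    - { max: 30, stars: 1.0 }
    - { max: null, stars: 0.5 }
healthier_min_stars: 3.5
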