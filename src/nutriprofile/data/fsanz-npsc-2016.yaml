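# FSANZ Nutrient Profiling Scoring Criterion (Standard 1.2.7 / Schedule of
# the ANZ Food Standards Code), gating nutrition & health claims.
# Category 1: beverages; category 2: general foods; category 3: oils/spreads
# and cheese with >= 320 mg calcium/100 g (extended saturated-fat range).
model: fsanz
version: "NPSC-2016"
categories: [npsc_1, npsc_2, npsc_3]
negative:
  energy:
    comparator: gt
    thresholds: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sat_fat:
    comparator: gt
    thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sat_fat_extended: # category 3 only: continues to 30 points
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
  fibre: # extended table (to 15 points)
    comparator: gt
    thresholds:
      [0.9, 1.9, 2.8, 3.7, 4.7, 5.4, 6.3, 7.3, 8.4, 9.7, 11.2, 13, 15, 17.3, 20]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
  protein: # extended table (to 15 points)
    comparator: gt
    thresholds:
      [1.6, 3.2, 4.8, 6.4, 8.0, 9.6, 11.6, 13.9, 16.7, 20, 24, 28.9, 34.7, 41.6, 50]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
extended_sat_fat_categories: [npsc_3]
protein_suppression:
  baseline_min: 13 # protein cannot score when baseline >= 13 ...
  fvn_exempt_points: 5 # ... unless fvn scores 5 points
  exempt_categories: []
pass_below: # eligible to carry claims iff score < cut-off
  npsc_1: 1
  npsc_2: 4
  npsc_3: 28
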