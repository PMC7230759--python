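# Nutri-Score 2017 foods algorithm (Sante publique France / HCSP).
# Component points: a value scores points[k-1] where k is the number of
# thresholds it exceeds ("gt") or reaches ("ge"); 0 points below the first.
model: nutriscore
version: "2017-foods"
categories: [general_food, cheese, added_fats]
negative:
  energy: # kJ/100 g
    comparator: gt
    thresholds: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sat_fat: # g/100 g
    comparator: gt
    thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sat_fat_ratio: # 100 * sat_fat / total_fat; replaces sat_fat for added_fats
    comparator: ge
    thresholds: [10, 16, 22, 28, 34, 40, 46, 52, 58, 64]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  total_sugars: # g/100 g
    comparator: gt
    thresholds: [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sodium: # mg/100 g
    comparator: gt
    thresholds: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
    points: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
positive:
  fvn: # % fruit/vegetable/nut/legume
    comparator: gt
    thresholds: [40, 60, 80]
    points: [1, 2, 5]
  fibre: # g/100 g; AOAC variant (EU labels declare AOAC fibre)
    comparator: gt
    thresholds: [0.9, 1.9, 2.8, 3.7, 4.7]
    points: [1, 2, 3, 4, 5]
  fibre_nsp: # NSP variant, selectable via the fibre_variant switch
    comparator: gt
    thresholds: [0.7, 1.4, 2.1, 2.8, 3.5]
    points: [1, 2, 3, 4, 5]
  protein: # g/100 g
    comparator: gt
    thresholds: [1.6, 3.2, 4.8, 6.4, 8.0]
    points: [1, 2, 3, 4, 5]
fibre_variant: fibre # fibre | fibre_nsp
protein_suppression:
  negative_min: 11 # suppress protein when N-total >= 11 ...
  fvn_exempt_points: 5 # ... unless fvn scores the maximum 5 points
  exempt_categories: [cheese] # protein always counts for cheese
grades: # final score -> letter, first band whose upper bound holds
  - { max: -1, grade: A }
  - { max: 2, grade: B }
  - { max: 10, grade: C }
  - { max: 18, grade: D }
  - { max: null, grade: E }
healthier_grades: [A, B]
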