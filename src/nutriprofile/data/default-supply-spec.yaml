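# Default synthetic food-supply specification.
#
# Emulates the category structure of a national branded-food composition
# survey over the five studied categories (seven leaf codes).  Nutrients are
# drawn from truncated normals (or uniforms) per 100 g; hard bounds keep
# every draw inside the panel invariants.  Saturated fat is clipped to total
# fat after drawing; cooking-oil energy is tied to fat at 37 kJ/g.  Sales are
# log-normal (heavy-tailed); `bias` couples log-sales to a healthiness index
# (the negated Ofcom score, standardised within category), so bias < 0 makes
# market leaders less healthy than the category average.
version: "1.0"
sales: { mu: 4.0, sigma: 1.2 }
categories:
  breakfast_cereals:
    n: 180
    nutrients:
      energy: { mean: 1620, sd: 150, lo: 1150, hi: 2000 }
      total_fat: { mean: 6.0, sd: 4.0, lo: 0.5, hi: 25 }
      sat_fat: { mean: 2.0, sd: 1.6, lo: 0.1, hi: 12 }
      total_sugars: { mean: 18, sd: 9, lo: 1, hi: 45 }
      salt: { mean: 0.5, sd: 0.3, lo: 0.0, hi: 1.5 }
      fibre: { mean: 6.0, sd: 3.0, lo: 1, hi: 15 }
      protein: { mean: 9.0, sd: 2.0, lo: 5, hi: 16 }
    wholegrain_fraction: 0.4
    wholegrain_range: [30, 100]
    wholegrain_fibre: { mean: 9.0, sd: 2.0, lo: 5, hi: 16 }
    added_sugar_baseline: 1.0
    sweetener_prob: 0.05
    sales_bias: -0.8
  pasta:
    n: 160
    nutrients:
      energy: { mean: 1520, sd: 60, lo: 1350, hi: 1700 }
      total_fat: { mean: 1.8, sd: 0.8, lo: 0.3, hi: 8 }
      sat_fat: { mean: 0.4, sd: 0.2, lo: 0.05, hi: 2 }
      total_sugars: { mean: 3.0, sd: 1.5, lo: 0.5, hi: 8 }
      salt: { mean: 0.03, sd: 0.05, lo: 0.0, hi: 0.4 }
      fibre: { mean: 3.0, sd: 0.8, lo: 1, hi: 6 }
      protein: { mean: 12.5, sd: 1.0, lo: 10, hi: 16 }
    wholegrain_fraction: 0.3
    wholegrain_range: [50, 100]
    wholegrain_fibre: { mean: 7.5, sd: 1.5, lo: 5, hi: 12 }
    sweetener_prob: 0.0
    sales_bias: 0.0
  cheese:
    n: 190
    nutrients:
      energy: { mean: 1350, sd: 250, lo: 700, hi: 1900 }
      total_fat: { mean: 26, sd: 6, lo: 8, hi: 40 }
      sat_fat: { mean: 17, sd: 4, lo: 5, hi: 28 }
      total_sugars: { mean: 1.0, sd: 0.8, lo: 0.0, hi: 3.5 }
      salt: { mean: 1.5, sd: 0.5, lo: 0.4, hi: 3.0 }
      fibre: { mean: 0.0, sd: 0.0, lo: 0.0, hi: 0.0 }
      protein: { mean: 22, sd: 4, lo: 10, hi: 32 }
    calcium: { mean: 700, sd: 150, lo: 250, hi: 1100 }
    sweetener_prob: 0.0
    sales_bias: 0.8
  yoghurt_plain:
    n: 60
    nutrients:
      energy: { mean: 270, sd: 60, lo: 150, hi: 450 }
      total_fat: { mean: 3.3, sd: 1.4, lo: 0.1, hi: 10 }
      sat_fat: { mean: 2.2, sd: 0.9, lo: 0.05, hi: 7 }
      total_sugars: { mean: 4.7, sd: 0.8, lo: 3, hi: 7 }
      salt: { mean: 0.13, sd: 0.04, lo: 0.02, hi: 0.3 }
      fibre: { mean: 0.0, sd: 0.0, lo: 0.0, hi: 0.0 }
      protein: { mean: 4.3, sd: 0.8, lo: 2.8, hi: 7 }
    calcium: { mean: 120, sd: 25, lo: 60, hi: 200 }
    added_sugar_baseline: 4.7 # lactose: plain yoghurt has no added sugar
    sweetener_prob: 0.0
    sales_bias: 0.0
  yoghurt_flavoured:
    n: 120
    nutrients:
      energy: { mean: 420, sd: 80, lo: 250, hi: 650 }
      total_fat: { mean: 2.8, sd: 1.2, lo: 0.1, hi: 8 }
      sat_fat: { mean: 1.8, sd: 0.8, lo: 0.05, hi: 5.5 }
      total_sugars: { mean: 12.5, sd: 3.0, lo: 6, hi: 22 }
      salt: { mean: 0.13, sd: 0.04, lo: 0.02, hi: 0.3 }
      fibre: { mean: 0.2, sd: 0.3, lo: 0.0, hi: 1.5 }
      protein: { mean: 3.8, sd: 0.7, lo: 2.5, hi: 6 }
    calcium: { mean: 110, sd: 25, lo: 50, hi: 190 }
    added_sugar_baseline: 4.5
    sweetener_prob: 0.1
    sales_bias: 0.0
  yoghurt_drink_flavoured:
    n: 40
    nutrients:
      energy: { mean: 320, sd: 60, lo: 180, hi: 500 }
      total_fat: { mean: 1.3, sd: 0.7, lo: 0.05, hi: 4 }
      sat_fat: { mean: 0.9, sd: 0.5, lo: 0.02, hi: 3 }
      total_sugars: { mean: 11.0, sd: 2.5, lo: 5, hi: 18 }
      salt: { mean: 0.1, sd: 0.04, lo: 0.02, hi: 0.25 }
      fibre: { mean: 0.1, sd: 0.2, lo: 0.0, hi: 1.0 }
      protein: { mean: 2.9, sd: 0.5, lo: 1.8, hi: 4.5 }
    calcium: { mean: 100, sd: 20, lo: 50, hi: 170 }
    added_sugar_baseline: 4.0
    sweetener_prob: 0.15
    sales_bias: 0.0
  cooking_oil:
    n: 50
    nutrients:
      total_fat: { uniform: [91, 100] }
      sat_fat: { mean: 15, sd: 10, lo: 7, hi: 92 }
      total_sugars: { mean: 0, sd: 0, lo: 0, hi: 0 }
      salt: { mean: 0, sd: 0, lo: 0, hi: 0 }
      fibre: { mean: 0, sd: 0, lo: 0, hi: 0 }
      protein: { mean: 0, sd: 0, lo: 0, hi: 0 }
    energy_from_fat: true # energy = 37 kJ per g fat
    sweetener_prob: 0.0
    sales_bias: 0.0
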