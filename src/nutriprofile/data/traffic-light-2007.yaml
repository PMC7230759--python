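# UK FSA front-of-pack traffic-light bands, per 100 g (previous / 2007
# version, still applied in Slovenia).  A nutrient is green at or below
# green_max, red strictly above red_above, amber in between.  The
# harmonised "healthier" verdict is: no red light.
model: traffic_light
version: "FSA-2007-per100g"
bands:
  total_fat: { green_max: 3.0, red_above: 17.5 }
  sat_fat: { green_max: 1.5, red_above: 5.0 }
  total_sugars: { green_max: 5.0, red_above: 22.5 }
  salt: { green_max: 0.3, red_above: 1.5 }
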