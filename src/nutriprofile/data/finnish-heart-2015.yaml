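# Finnish Heart Symbol ("Sydanmerkki", Finnish Heart Association), per 100 g.
model: finnish_heart
version: "2015"
categories:
  breakfast_cereals:
    rules:
      - { quantity: total_fat, op: "<=", limit: 5 }
      - { quantity: total_sugars, op: "<=", limit: 16 }
      - { quantity: fibre, op: ">=", limit: 6 }
      - { quantity: salt, op: "<=", limit: 0.7 }
  pasta:
    rules:
      - { quantity: fibre, op: ">=", limit: 6 }
      - { quantity: salt, op: "<=", limit: 0.7 }
      - { quantity: total_fat, op: "<=", limit: 5 }
  cheese:
    rules:
      - { quantity: total_fat, op: "<=", limit: 17 }
      - { quantity: salt, op: "<=", limit: 1.2 }
  yoghurt_plain:
    rules:
      - { quantity: total_fat, op: "<=", limit: 1 }
      - { quantity: added_sugars, op: "<=", limit: 0, note: "unflavoured: no added sugar" }
      - { quantity: salt, op: "<=", limit: 1.0 }
  yoghurt_flavoured:
    rules:
      - { quantity: total_fat, op: "<=", limit: 1 }
      - { quantity: total_sugars, op: "<=", limit: 12 }
      - { quantity: salt, op: "<=", limit: 1.0 }
  yoghurt_drink_flavoured: # fermented milk drink group
    rules:
      - { quantity: total_fat, op: "<=", limit: 1 }
      - { quantity: total_sugars, op: "<=", limit: 12 }
      - { quantity: salt, op: "<=", limit: 1.0 }
  cooking_oil:
    rules:
      - { quantity: sat_fat_share_pct, op: "<=", limit: 20, note: "% of total fat" }
      - { quantity: trans_fat, op: "<=", limit: 1 }
      - { quantity: salt, op: "<=", limit: 1.0 }
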