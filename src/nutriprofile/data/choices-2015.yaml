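# Dutch Choices symbol (international criteria, 2015 revision), per 100 g.
model: choices
version: "2015"
categories:
  breakfast_cereals:
    rules:
      - { quantity: sat_fat, op: "<=", limit: 3 }
      - { quantity: trans_fat, op: "<=", limit: 0.14 }
      - { quantity: added_sugars, op: "<=", limit: 13 }
      - { quantity: salt, op: "<=", limit: 1.0 }
      - { quantity: fibre, op: ">=", limit: 6 }
  pasta:
    rules:
      - { quantity: sat_fat, op: "<=", limit: 1.1 }
      - { quantity: trans_fat, op: "<=", limit: 0.1 }
      - { quantity: added_sugars, op: "<=", limit: 2.5 }
      - { quantity: salt, op: "<=", limit: 0.25 }
      - { quantity: fibre, op: ">=", limit: 3.3 }
  cheese:
    rules:
      - { quantity: sat_fat, op: "<=", limit: 16 }
      - { quantity: salt, op: "<=", limit: 1.7 }
  yoghurt_plain:
    rules:
      - { quantity: sat_fat, op: "<=", limit: 1.4 }
      - { quantity: added_sugars, op: "<=", limit: 5 }
      - { quantity: salt, op: "<=", limit: 0.2 }
  yoghurt_flavoured:
    rules:
      - { quantity: sat_fat, op: "<=", limit: 1.4 }
      - { quantity: added_sugars, op: "<=", limit: 5 }
      - { quantity: salt, op: "<=", limit: 0.2 }
  yoghurt_drink_flavoured: # fermented milk drink group
    rules:
      - { quantity: sat_fat, op: "<=", limit: 1.4 }
      - { quantity: added_sugars, op: "<=", limit: 5 }
      - { quantity: salt, op: "<=", limit: 0.2 }
  cooking_oil:
    rules:
      - { quantity: sat_fat, op: "<=", limit: 30 }
      - { quantity: trans_fat, op: "<=", limit: 1.3 }
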