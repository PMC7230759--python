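# Mapping from the seven leaf food categories to each model's internal
# category.  "default" catches every leaf code not listed explicitly.
# The FSANZ cheese entry is conditional on declared calcium (NPSC category 3
# covers cheese with >= 320 mg calcium / 100 g); products without a calcium
# declaration fall back to the general-food category.
version: "2020-scope"
models:
  nutriscore:
    cooking_oil: added_fats
    cheese: cheese
    default: general_food
  ofcom:
    yoghurt_drink_flavoured: drink
    default: food
  hsr:
    cooking_oil: oils
    cheese: dairy_cheese
    yoghurt_plain: dairy_food
    yoghurt_flavoured: dairy_food
    yoghurt_drink_flavoured: dairy_food
    default: food
  fsanz:
    cooking_oil: npsc_3
    yoghurt_drink_flavoured: npsc_1
    cheese:
      calcium_at_least: 320
      then: npsc_3
      else: npsc_2
    default: npsc_2
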