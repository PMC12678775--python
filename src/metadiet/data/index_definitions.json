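{
  "comment": "Component lists for the seven a priori dietary indices, expressed over the 20 synthetic food and beverage groups. Components may sum several group columns; 'nutrient:' prefixed entries reference nutrient-table columns.",
  "pdi_family": {
    "healthy_plant": [
      ["whole_grains"], ["fruits"], ["vegetables"], ["nuts_seeds"],
      ["legumes"], ["vegetable_oils"], ["tea_coffee"]
    ],
    "less_healthy_plant": [
      ["fruit_juice"], ["refined_grains"], ["potatoes"],
      ["sugary_beverages"], ["sweets_desserts"]
    ],
    "animal": [
      ["red_meat", "processed_meat"], ["poultry"], ["fish_seafood"],
      ["eggs"], ["dairy_lowfat", "dairy_highfat"], ["alcohol"]
    ]
  },
  "dash": {
    "encouraged": [
      ["fruits"], ["vegetables"], ["nuts_seeds", "legumes"],
      ["whole_grains"], ["dairy_lowfat"]
    ],
    "discouraged": [
      ["nutrient:sodium_mg"], ["red_meat", "processed_meat"],
      ["sugary_beverages"]
    ]
  },
  "amed": {
    "above_median": [
      ["vegetables"], ["fruits"], ["legumes"], ["nuts_seeds"],
      ["whole_grains"], ["fish_seafood"], ["vegetable_oils"]
    ],
    "below_median": [["red_meat", "processed_meat"]],
    "alcohol_group": "alcohol",
    "alcohol_window_female": [5.0, 15.0],
    "alcohol_window_male": [10.0, 25.0]
  },
  "plant_meat": {
    "plant_groups": [
      "fruits", "vegetables", "legumes", "nuts_seeds", "whole_grains",
      "refined_grains", "potatoes", "fruit_juice", "vegetable_oils"
    ],
    "meat_groups": ["red_meat", "processed_meat", "poultry", "fish_seafood"]
  }
}
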