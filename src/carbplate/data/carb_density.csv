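food_class,carb_density_g_per_ml,n_source_entries,source_note
pasta,0.17,6,"synthetic toy value: cooked pasta ~25 g carb/100 g at ~0.7 g/ml served density"
potatoes,0.13,5,"synthetic toy value: boiled potato ~17 g carb/100 g at ~0.75 g/ml"
meat,0.01,8,"synthetic toy value: plain cooked meat carries almost no carbohydrate"
breaded,0.10,4,"synthetic toy value: breading contributes ~14 g carb/100 g at ~0.7 g/ml"
rice,0.22,6,"synthetic toy value: cooked rice ~28 g carb/100 g at ~0.8 g/ml"
green_salad_vegetables,0.03,9,"synthetic toy value: leafy salads and cooked vegetables, ~4 g carb/100 g"
mashed_potatoes,0.15,3,"synthetic toy value: mash ~16 g carb/100 g at ~0.95 g/ml"
carrots,0.07,4,"synthetic toy value: cooked carrots ~8 g carb/100 g at ~0.9 g/ml"
beans,0.13,5,"synthetic toy value: cooked beans ~21 g carb/100 g at ~0.6 g/ml"
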