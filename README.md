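# carbplate

Two-view carbohydrate estimation for plated meals.

People with type 1 diabetes dose prandial insulin by counting the
carbohydrates on their plate, and they systematically misjudge it —
errors of ±20 g and more measurably disturb post-meal blood glucose.
`carbplate` implements the computer-vision pipeline of a smartphone-style
meal assessment system as a tested Python library and CLI: from two RGB
photographs of one plated meal (one taken from almost directly above,
one tilted ~15°, with a credit-card-sized reference card beside the
plate) it

1. detects the elliptical plate border from image edges (RANSAC over
   5-point conic fits + least-squares refinement),
2. segments the food items inside the plate (seeded color region
   growing in CIELAB, region merging by color distance and mutual
   border, plate-background exclusion; automatic grid seeding with an
   interactive seeded fallback),
3. recognizes each item among nine broad classes (pasta, potatoes,
   meat, breaded, rice, green salad/vegetables, mashed potatoes,
   carrots, beans) with color + LBP texture histograms and a
   probability-calibrated RBF SVM, returning a confidence-ranked list
   for one-tap manual correction,
4. reconstructs the meal in 3D from the two views (keypoint matching,
   dominant-plane pose recovery, rectified dense block matching), fixes
   the metric scale from the reference card, and integrates each item's
   volume `V = Σ cell_area · height` above a robustly fitted plate
   plane,
5. converts volumes to grams of carbohydrate, `carbs = V · ρ_class`,
   with a per-class mean carbohydrate density table (g carb / ml).

It also ships a seeded synthetic scene renderer with exact ground truth
(so every stage is testable without photographs) and the evaluation
statistics used for with/without-system studies: per-meal errors, the
±20 g clinical band, under/over-estimation balance, success rates,
outlier-participant exclusion, size-stratified summaries, and a
Mann-Whitney U test (exact by enumeration for small samples).

## Worked example

Render two synthetic meals, train the food classifier on synthetic
single-item renders, and estimate one meal end to end:

```bash
carbplate synth --out scenes --n-scenes 2 --seed 5
carbplate train --out model.joblib --n-per-class 20 --seed 1
carbplate estimate --scene scenes/scene_0000 --model model.joblib
```

prints (abbreviated):

```json
{
 "stage_statuses": {"capture": "ok", "plate": "ok", "segmentation": "ok",
                    "recognition": "ok", "reconstruction": "ok", "volume": "ok"},
 "meal": {
  "items": [
   {"region_id": 1, "food_class": "carrots",        "volume_ml": 72.4, "carbs_g": 5.07},
   {"region_id": 2, "food_class": "mashed_potatoes", "volume_ml": 43.6, "carbs_g": 6.54},
   {"region_id": 3, "food_class": "breaded",         "volume_ml": 35.5, "carbs_g": 3.55}
  ],
  "total_carbs_g": 15.16
 }
}
```

Every stage ran automatically; each item's reconstructed volume (ml)
was multiplied by its class's carbohydrate density from the packaged
toy table, and the meal totals 15.2 g of carbohydrate. A wrong
recognition can be corrected with `--override 2=rice`, which changes
the total by exactly `(ρ_rice − ρ_mashed) × 43.6 ml`.

Study-style evaluation of a per-meal estimate table (columns
`meal_id,participant_id,size,true_g,self_g,system_g`):

```bash
carbplate stats --input meals.csv --band 20
```

```text
n = 30 meals, clinical band = +/-20 g

                    Abs error g, mean (SD)  Abs % error, mean (SD)   |err| < band, n (%)
Without system              25.31 (19.42)            50.3 (39.1)          13/30 (43.3)
With system                  7.59 (5.32)            19.0 (22.0)          30/30 (100.0)

Mann-Whitney U = 722, two-sided p = 5.971e-05
```

Here the simulated self-estimates miss by 25.3 g on average and land
inside the ±20 g band in 43% of meals, while the system's estimates
miss by 7.6 g and always stay in band; the rank test rejects equality
of the absolute-error distributions.

See `docs/methods.md` for the models, parameter defaults, numerical
choices, and what the synthetic world does and does not emulate.

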