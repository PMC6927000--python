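# RNI 2017 nutrient bounds for pregnant women, per trimester.
# [lower, upper]; upper null = unbounded (no tolerable upper limit used).
# Units are the canonical nutrient units (kcal, g, mg, RE).
1:
  energy_kcal: [1680, 1880]
  protein_g: [53, 90.5]
  carb_g: [185, 305.5]
  fat_g: [54, 65]
  fibre_g: [20, 30]
  vitA_RE: [800, 2800]
  vitC_mg: [80, 2000]
  vitB1_mg: [1.4, null]
  vitB2_mg: [1.4, null]
  vitB3_mg: [18, 35]
  sodium_mg: [1500, 2300]
  potassium_mg: [4700, null]
  calcium_mg: [1000, 2500]
  iron_mg: [20, 29]
  phosphorus_mg: [700, 3500]
2:
  energy_kcal: [1880, 2080]
  protein_g: [60.5, 98]
  carb_g: [210, 338]
  fat_g: [60, 71]
  fibre_g: [20, 30]
  vitA_RE: [800, 2800]
  vitC_mg: [80, 2000]
  vitB1_mg: [1.4, null]
  vitB2_mg: [1.4, null]
  vitB3_mg: [18, 35]
  sodium_mg: [1500, 2300]
  potassium_mg: [4700, null]
  calcium_mg: [1000, 2500]
  iron_mg: [20, 29]
  phosphorus_mg: [700, 3500]
3:
  energy_kcal: [2070, 2270]
  protein_g: [77.5, 115]
  carb_g: [233.8, 368.9]
  fat_g: [65, 78]
  fibre_g: [20, 30]
  vitA_RE: [800, 2800]
  vitC_mg: [80, 2000]
  vitB1_mg: [1.4, null]
  vitB2_mg: [1.4, null]
  vitB3_mg: [18, 35]
  sodium_mg: [1500, 2300]
  potassium_mg: [4700, null]
  calcium_mg: [1000, 2500]
  iron_mg: [20, 29]
  phosphorus_mg: [700, 3500]
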