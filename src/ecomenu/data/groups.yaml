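# Target-group lunch requirement profiles.  PLACEHOLDER editable values:
# the national guide's exact per-group targets are not published with this
# package; replace with institutional values before operational use.
#
# Macro gram windows derive from 8-30 %E protein, 15-50 %E fat,
# 30-70 %E carbohydrate at each group's lunch energy target.
preschool:
  energy_target_kcal: 450
  energy_tolerance: 0.10
  macro_targets:
    protein_g: [9.0, 33.8]
    fat_g: [7.5, 25.0]
    carb_g: [33.8, 78.8]
  n_meal_slots: 3
  frequency_rules: {}
hospital:
  energy_target_kcal: 750
  energy_tolerance: 0.10
  macro_targets:
    protein_g: [15.0, 56.3]
    fat_g: [12.5, 41.7]
    carb_g: [56.3, 131.3]
  n_meal_slots: 4
  frequency_rules: {}
nursing_home:
  energy_target_kcal: 650
  energy_tolerance: 0.10
  macro_targets:
    protein_g: [13.0, 48.8]
    fat_g: [10.8, 36.1]
    carb_g: [48.8, 113.8]
  n_meal_slots: 3
  frequency_rules: {}
prison:
  energy_target_kcal: 800
  energy_tolerance: 0.10
  macro_targets:
    protein_g: [16.0, 60.0]
    fat_g: [13.3, 44.4]
    carb_g: [60.0, 140.0]
  n_meal_slots: 3
  frequency_rules: {}
workplace:
  energy_target_kcal: 850
  energy_tolerance: 0.10
  macro_targets:
    protein_g: [17.0, 63.8]
    fat_g: [14.2, 47.2]
    carb_g: [63.8, 148.8]
  n_meal_slots: 3
  frequency_rules: {}
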