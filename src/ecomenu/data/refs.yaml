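# Reference baskets for nutrient profiling.  Editable data, not code.
#
# nrf_dv / nrf_mrv: FDA adult daily values and maximal recommended values
# for the NRF 9.3 qualifying (9) and disqualifying (3) baskets.
# sain_rv / lim_mrv: Darmon et al. SAIN-LIM recommended / maximal values
# (SAIN basic 5-nutrient basket).
nrf_dv:
  protein_g: 50.0
  fiber_g: 28.0
  vita_ug: 900.0
  vitc_mg: 90.0
  vite_mg: 15.0
  calcium_mg: 1300.0
  iron_mg: 18.0
  magnesium_mg: 420.0
  potassium_mg: 4700.0
nrf_mrv:
  satfat_g: 20.0
  addedsugar_g: 50.0
  sodium_mg: 2300.0
sain_rv:
  protein_g: 65.0
  fiber_g: 30.0
  vitc_mg: 110.0
  calcium_mg: 900.0
  iron_mg: 12.5
lim_mrv:
  satfat_g: 22.0
  addedsugar_g: 50.0
  sodium_mg: 3153.0
energy_basis: 100.0   # kcal basis for NRF 9.3 and SAIN
mass_basis: 100.0     # g basis for LIM
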