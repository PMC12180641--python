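# Default configuration.
#
# Geometry, temporal resolution, seeding fraction, division probabilities,
# voiding cadence/washout, contact-inhibition factor and the apoptosis band
# are fixed biological/numerical constants of the model.  Cell sizes, energy
# weights, contact energies, growth rates and the Metropolis temperature are
# calibrated defaults (see scripts/calibrate_temperature.py): contact
# energies are ordered so that free-floating cells sort into an onion-ring
# structure BM > P/B > I > U > medium (with complete wetting of the membrane
# by basal/progenitor cells and of the tissue surface by umbrella cells),
# and growth rates were tuned so the best lineage models heal in < 5 days
# and hold a stratified ~85 um tissue near the voiding washout balance.

lattice:
  width_um: 800.0
  height_um: 150.0
  px_per_um: 0.8        # -> 640 x 120 px
  bm_rows: 2

engine:
  temperature: 22.0
  mcs_per_day: 500
  lambda_adhesion: 1.0
  # rasterized discs expose ~3.2 Moore faces per unit of circumference
  surface_scale: 3.2

cell_types:
  progenitor:
    d_min_um: 8.0
    d_max_um: 12.0
    lambda_volume: 5.0
    lambda_surface: 2.0
    growth_rate: 0.05          # fraction of Vmax per day (contact-inhibited)
    apoptosis_chance: 1.0e-7   # per day
  basal:
    d_min_um: 8.0
    d_max_um: 12.0
    lambda_volume: 5.0
    lambda_surface: 2.0
    growth_rate: 0.035
    apoptosis_chance: 1.0e-6
  intermediate:
    d_min_um: 18.0
    d_max_um: 20.0
    lambda_volume: 5.0
    lambda_surface: 2.0
    growth_rate: 0.02
    apoptosis_chance: 1.0e-5
  umbrella:
    d_min_um: 10.0
    d_max_um: 26.0
    lambda_volume: 4.0
    lambda_surface: 0.5
    growth_rate: 0.0
    apoptosis_chance: 1.8e-4

# 21 surface-tension values (small = high adhesion).  gamma(B,BM) < 0 ->
# basal/progenitor cells wet the membrane as a monolayer; umbrella cells
# present the lowest-energy interface to the medium and spread over the
# tissue surface.
contact_energies:
  medium-medium: 0.0
  bm-bm: 0.0
  bm-medium: 40.0
  progenitor-bm: 1.0
  basal-bm: 1.0
  intermediate-bm: 16.0
  umbrella-bm: 28.0
  progenitor-medium: 30.0
  basal-medium: 30.0
  intermediate-medium: 24.0
  umbrella-medium: 4.0
  progenitor-progenitor: 10.0
  progenitor-basal: 10.0
  basal-basal: 10.0
  progenitor-intermediate: 12.0
  basal-intermediate: 12.0
  intermediate-intermediate: 6.0
  progenitor-umbrella: 16.0
  basal-umbrella: 16.0
  intermediate-umbrella: 8.0
  umbrella-umbrella: 8.0

lineage:
  p_sym: 0.05
  p_asym: 0.9
  voiding_interval_hours: 6.0
  voiding_washout_p: 0.02
  differentiation_interval_hours: 6.0
  medium_contact_faces: 12
  contact_inhibition_factor: 50.0
  division_orientation: principal
  division_trigger_ratio: 0.9

init:
  progenitor_fraction: 0.12
  cell_width_px: 6
  cell_height_px: 6
  max_retries: 1000

fitness:
  column_spacing_um: 25.0
  thickness_um: 85.0
  fraction_basal: 0.10
  fraction_intermediate: 0.67
  fraction_umbrella: 0.23
  sample_interval_days: 0.5
  elib_mode: strict
  eopt_min_layers: 3
  eopt_max_layers: 7
  min_layer_rows: 2

classify:
  window_start_day: 20.0
  min_days: 100.0
  stable_slope_pct_per_100d: 2.0
  chaotic_fa_threshold: 0.6
  atrophy_final_frac: 0.05

# Per-lineage-model parameter adjustments.  Models without basal
# proliferation (BCD + non-dividing intermediates) need a faster progenitor
# cycle, or the few seeded progenitors are washed out before the protective
# umbrella cover forms.
model_overrides:
  SSD/BCD/ICD:
    cell_types:
      progenitor:
        growth_rate: 0.15
  SPA/BCD/ICD:
    cell_types:
      progenitor:
        growth_rate: 0.15

schedule:
  duration_days: 720.0
  snapshot_every_days_early: 1.0
  snapshot_every_days_late: 10.0
  snapshot_switch_day: 20.0
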