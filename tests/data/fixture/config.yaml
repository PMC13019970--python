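n_intervention_homes: 2
n_control_homes: 1
weeks:
- -2
- 0
- 2
- 4
seeding_weeks:
- 0
strata:
  entrance_IBZ:
  - settled_dust
  - entrance
  - IBZ
  - 1.0
  entrance_ABZ:
  - settled_dust
  - entrance
  - ABZ
  - 0.7
  LR_floor:
  - floor_dust
  - floor
  - none
  - 0.25
  outdoor:
  - settled_dust
  - outdoor
  - none
  - 0.0
richness:
  soil: 12
  human: 10
  outdoor: 10
  home: 12
profile_concentration:
  soil: 0.4
  human: 0.6
  outdoor: 0.5
  home: 0.7
soil_outdoor_overlap: 0.05
amplitudes:
- 0.2
- 0.1
decay_rate: 0.3466
background_weights:
  human: 0.45
  outdoor: 0.15
  home: 0.4
outdoor_background_weights:
  human: 0.05
  outdoor: 0.85
  home: 0.1
seasonal_start_week: 6
seasonal_slope: 0.01
depth_mean: 3000.0
depth_sigma: 0.25
overdispersion: 2000.0
n_aliquots_per_event: 2
aliquot_depth_mean: 3000.0
n_blanks: 2
n_contaminants: 2
contaminant_weight: 5.0e-05
blank_depth_mean: 800.0
kingdom: bacteria
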