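# Lamotrigine (LTG) built-in profile.
# Physicochemistry/biopharmaceutics, UGT enzyme kinetics and the gestational
# intrinsic-clearance trajectory used by the pregnancy model and the DDI module.
# Peff is entered on the human jejunal scale (cm/s).
drug:
  name: LTG
  molecular_weight: 256.09
  log_p: 1.70
  pka: 4.41
  ionization_class: monoprotic_base
  # measured value at the pH of least ionization (pH 8.0)
  intrinsic_solubility: 0.21
  solubility_factor: 12.09
  solubility_curve: [[1.2, 2.54], [4.5, 0.38], [6.8, 0.24], [7.4, 0.25], [8.0, 0.21]]
  fassgf_solubility: 3.48
  fassif_solubility: 0.35
  blood_plasma_ratio: 1.00
  fraction_unbound_plasma: 0.45
  effective_permeability: 7.76e-4
  diffusion_coefficient: 0.84e-5
  mean_particle_radius: 25.0
  particle_density: 1.20
  dose_volume: 250.0
  precipitation_time: 900.0
  dosage_form: IR_tablet
calibration:
  # compartmental (plasma-level) anchors the disposition is calibrated to
  vss_target_l_per_kg: 1.13
  total_clearance_l_per_h: 2.09
enzymes:
  - enzyme: UGT1A3
    location: liver
    vmax: 0.0000681   # mg/s per mg enzyme
    km: 18.83         # µg/mL
    clint: 0.3411     # L/h, non-pregnant
    fm: 8.63          # % of total elimination
    turnover: 0.0005  # 1/min
  - enzyme: UGT1A4
    location: liver
    vmax: 0.00466
    km: 147.95
    clint: 3.1564
    fm: 79.90
    turnover: 0.0005
# Clint (L/h) and fm (%) by gestational week; week 0 = non-pregnant
gestational_clint:
  UGT1A3:
    - [0, 0.3411, 8.63]
    - [10, 0.299, 8.5]
    - [20, 0.288, 8.46]
    - [30, 0.274, 8.4]
    - [40, 0.261, 8.34]
  UGT1A4:
    - [0, 3.1564, 79.90]
    - [10, 2.77, 78.65]
    - [20, 2.67, 78.28]
    - [30, 2.53, 77.73]
    - [40, 2.41, 77.2]
interactions: []
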