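# Efavirenz (EFV) built-in profile.
# EFV is entered as reported in the source compound table (base, pKa 10.2);
# chemically it is a weak NH-acid, so ionization_class is configurable.
# fm percentages for the hepatic pathways are not reported for EFV; the split
# below follows the CYP2B6-dominant mechanistic literature (see docs/methods.md)
# and only sets the split -- the calibrated total clearance sets the magnitude.
drug:
  name: EFV
  molecular_weight: 315.68
  log_p: 4.6
  pka: 10.2
  ionization_class: monoprotic_base
  intrinsic_solubility: 9.0e-3   # mg/mL at pH 6.9641
  solubility_factor: 4342.8
  solubility_curve: [[6.9641, 9.0e-3]]
  fassgf_solubility: 6.5
  fassif_solubility: 5.0
  blood_plasma_ratio: 0.74
  fraction_unbound_plasma: 0.22
  effective_permeability: 1.07e-4
  diffusion_coefficient: 0.84e-5
  mean_particle_radius: 5.0
  particle_density: 1.20
  dose_volume: 250.0
  precipitation_time: 900.0
  dosage_form: IR_capsule
calibration:
  vss_target_l_per_kg: 1.341
  total_clearance_l_per_h: 3.496
  # fraction of absorbed drug escaping gut-wall (CYP3A4) metabolism the gut
  # enzyme amount is anchored to, consistent with the reported F ~ 88%
  gut_fg_target: 0.95
enzymes:
  - {enzyme: CYP2B6, location: liver, vmax: 0.050, km: 3.137, fm: 89.5, turnover: 0.0005}
  - {enzyme: CYP3A4, location: liver, vmax: 0.000562, km: 3.137, fm: 4.0, turnover: 0.0005}
  - {enzyme: CYP3A4, location: gut, vmax: 0.2, km: 3.137, fm: 0.0, turnover: 0.0005}
  - {enzyme: UGT1A4, location: liver, vmax: 0.0000208, km: 0.069, fm: 2.5, turnover: 0.0005}
  - {enzyme: UGT1A9, location: liver, vmax: 0.000111, km: 0.0051, fm: 4.0, turnover: 0.0005}
interactions:
  - {enzyme: CYP2B6, mechanism: induction, constant: 0.82, emax: 5.76, in_vitro_fu: 0.063, in_vitro_protein_conc: 0.0}
  - {enzyme: CYP3A4, mechanism: induction, constant: 1.0, emax: 9.9, in_vitro_fu: 0.063, in_vitro_protein_conc: 0.0}
  - {enzyme: UGT1A4, mechanism: reversible_inhibition, constant: 2.0, in_vitro_fu: 0.12, in_vitro_protein_conc: 0.5}
  - {enzyme: UGT1A9, mechanism: reversible_inhibition, constant: 9.4, in_vitro_fu: 0.12, in_vitro_protein_conc: 0.5}
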