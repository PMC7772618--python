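# Default energetics parameter set, version 0.1.
#
# PROVENANCE / CAVEAT: these constants are SYNTHETIC defaults chosen to be
# structurally faithful and numerically realistic for Western Hudson Bay
# polar bears, not transcriptions of published field-calibrated
# coefficient tables.  For field use, replace every block below with the
# published class-specific values and update `provenance`.
#
# Model structure (fixed by the code, constants supplied here):
#   ln(body_mass_kg) = intercept + girth*ln(girth_cm) + length*ln(length_cm)
#   lean_mass_kg     = structural_coeff_kg_per_m3 * (length_cm/100)^3
#   storage_mass_kg  = body_mass_kg - lean_mass_kg   (floored at 0)
#   storage_energy_MJ = storage_mass_kg *
#       (lipid_frac * lipid_energy + protein_frac * protein_energy)
#   energy_density_MJ_per_kg = storage_energy_MJ / lean_mass_kg

provenance: >-
  Synthetic structural defaults (v0.1), not field-calibrated.  Mass
  allometry ~ girth^2 * length scaled to adult-male ~400 kg; structural
  coefficient 14.9 kg/m^3 (cubic lean-mass allometry); lipid 39.3 and
  protein 17.8 MJ/kg combustion energies; per-class storage composition
  chosen so solitary adult females have the lipid-richest (most
  energy-dense) reserves and dependent young the leanest.

structural_coeff_kg_per_m3: 14.9
lipid_energy_MJ_per_kg: 39.3
protein_energy_MJ_per_kg: 17.8

mass_coefs:
  adult_male:                  {intercept: -9.625, girth: 2.0, length: 1.0}
  solitary_adult_female:       {intercept: -9.625, girth: 2.0, length: 1.0}
  adult_female_with_offspring: {intercept: -9.625, girth: 2.0, length: 1.0}
  subadult_male:               {intercept: -9.625, girth: 2.0, length: 1.0}
  subadult_female:             {intercept: -9.625, girth: 2.0, length: 1.0}
  yearling:                    {intercept: -9.625, girth: 2.0, length: 1.0}
  cub:                         {intercept: -9.625, girth: 2.0, length: 1.0}

storage_lipid_fraction:
  adult_male: 0.40
  solitary_adult_female: 0.55
  adult_female_with_offspring: 0.45
  subadult_male: 0.40
  subadult_female: 0.40
  yearling: 0.35
  cub: 0.30

storage_protein_fraction:
  adult_male: 0.23
  solitary_adult_female: 0.18
  adult_female_with_offspring: 0.20
  subadult_male: 0.22
  subadult_female: 0.22
  yearling: 0.22
  cub: 0.20
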