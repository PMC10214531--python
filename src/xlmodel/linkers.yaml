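# Default cross-linker chemistry table.
#
# Reactivities and linker/mono masses follow standard search-engine settings
# for these reagents.  Spacer lengths (A) are configuration, not ground truth:
# BS3/DSG/EDC use widely accepted values; KArGO and PDH defaults are plausible
# working values for these chemistries.  The Calpha-Calpha distance threshold
# of a reagent is spacer_length + tolerance; the 10 A tolerance absorbs
# side-chain lengths and backbone-position uncertainty.
#
# NTERM marks protein N-terminus reactivity (a pseudo-site on residue 1 of
# each chain).  Override any field from a user YAML via load_linker_config().

BS3:
  alpha_reactivity: [K, S, T, Y, NTERM]
  beta_reactivity: [K, S, T, Y, NTERM]
  spacer_length: 11.4
  linker_mass: 138.068
  mono_mass: 156.079
  tolerance: 10.0

DSG:
  alpha_reactivity: [K, S, T, Y, NTERM]
  beta_reactivity: [K, S, T, Y, NTERM]
  spacer_length: 7.7
  linker_mass: 96.021
  mono_mass: 114.032
  tolerance: 10.0

EDC:
  alpha_reactivity: [K, NTERM]
  beta_reactivity: [E, D]
  spacer_length: 0.0
  linker_mass: -18.011
  mono_mass: 0.0
  tolerance: 10.0

KArGO:
  alpha_reactivity: [K, NTERM]
  beta_reactivity: [R]
  spacer_length: 9.0
  linker_mass: 334.084
  mono_mass: 352.094
  tolerance: 10.0

PDH:
  alpha_reactivity: [E, D]
  beta_reactivity: [E, D]
  spacer_length: 9.2
  linker_mass: 152.106
  mono_mass: 170.117
  tolerance: 10.0
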