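# Downstream recovery/purification train (unit operations 2-11).
# Operation 1 is the fermentation and comes from the selected upstream
# option.  Five operations carry a fixed recovery yield; the other five
# (4, 6, 7, 9, 10) are the process-specific steps whose yields are varied
# in the sensitivity and sweep analyses.
flux_L_per_m2_h: 4.0
operations:
  - op_id: 2
    name: "Dilution with water"
    equipment: stainless_tank
    recovery_yield: 0.95
    volume_rule: add_equal_volume      # water addition 1:1, water not costed
  - op_id: 3
    name: "Biomass removal"
    equipment: centrifuge
    recovery_yield: 0.90
  - op_id: 4
    name: "Isopropanol precipitation"
    equipment: stainless_tank
    recovery_yield: variable
    volume_rule: add_equal_volume      # isopropanol addition 1:1
    liquid_additive: isopropanol
  - op_id: 5
    name: "Precipitate recovery"
    equipment: centrifuge
    recovery_yield: 0.90
  - op_id: 6
    name: "Resuspension in sodium acetate"
    equipment: stainless_tank
    recovery_yield: variable
    volume_rule: resuspend_to_reference  # resuspend into one fermentation volume
    solid_additive:
      name: sodium acetate
      dose_g_per_L: 30.0
      basis: volume_out
  - op_id: 7
    name: "Contaminant removal with silica gel"
    equipment: stainless_tank
    recovery_yield: variable
    solid_additive:
      name: silica gel
      dose_g_per_L: 30.0               # 3% w/v
      basis: volume_in
  - op_id: 8
    name: "Silica gel removal"
    equipment: centrifuge
    recovery_yield: 0.90
  - op_id: 9
    name: "Activated carbon filtration"
    equipment: flowthrough_filter
    recovery_yield: variable
  - op_id: 10
    name: "Ultrafiltration / diafiltration"
    equipment: tangential_ultrafilter
    recovery_yield: variable
    volume_rule: concentration_factor
    concentration_factor: 1.0          # 1X concentration: volume unchanged
    diavolumes: 5.0
  - op_id: 11
    name: "Sterile filtration"
    equipment: flowthrough_filter
    recovery_yield: 0.95
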