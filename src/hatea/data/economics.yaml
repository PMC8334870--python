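# Economic dataset: equipment cost regressions, bulk material prices,
# consumable cost rules and global assumptions.
#
# Equipment curves interpolate purchased-equipment cost over the 1-1,000 L
# operating window.  Sizes are litres for vessels, L/h throughput for
# centrifuges and m^2 of membrane for filters.
equipment_cost:
  bioreactor:             {form: power,        a: 34854.0,  b: 0.4058}
  centrifuge:             {form: scaled_power, a: 426720.0, ref: 600.0, b: 0.4}
  stainless_tank:         {form: linear,       slope: 42.195, intercept: 3052.2}
  flowthrough_filter:     {form: power,        a: 2229.6,   b: 0.4539}
  tangential_ultrafilter: {form: power,        a: 91036.0,  b: 0.3741}

# USD per kg, largest catalogue presentation (deliberate overestimate; the
# bulk-purchase discount variable compensates at large scales).
prices_usd_per_kg:
  glucose: 10.3
  peptone: 51.2
  MgSO4: 36.8
  MgSO4-7H2O: 40.8
  K2HPO4: 110.7
  starch: 16.6
  sucrose: 16.8
  yeast extract: 55.9
  K2SO4: 57.6
  Na2HPO4: 31.4
  Na2HPO4-12H2O: 31.4     # hydrate priced at the anhydrous catalogue entry
  FeSO4-7H2O: 92.6
  CaCl2: 63.7
  ZnCl2: 27.3
  CuSO4-5H2O: 54.7
  casein enzyme hydrolysate: 143.9
  NaCl: 10.9
  isopropanol: 20.8
  sodium acetate: 21.0
  (NH4)2SO4: 17.4
  KH2PO4: 32.9
  ZnSO4-7H2O: 104.2
  silica gel: 17.0

consumables:
  vessel_filter:          # single-use inlet filter fitted per vessel per batch
    slope_usd_per_L: 0.3058
    intercept_usd: 45.334
  flowthrough_filter:     # activated-carbon / sterile cartridges
    cost_usd_per_m2: 575.0
    lifetime_batches: 100
  uf_membrane:            # tangential-flow cassettes
    cost_usd_per_m2: 4621.0
    lifetime_batches: 100

assumptions:
  facility_factor: 6.0          # installed-facility (Lang-type) multiplier
  depreciation_years: 10        # straight-line, zero salvage
  labor_fraction: 0.15          # labor charged as 15% of total CoG
  operating_days_per_year: 200
  ipa_density_kg_per_L: 0.785
  dsp_overhead_h_per_op: 0.0    # extra prep/clean hours per downstream op
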