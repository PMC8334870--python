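# Upstream fermentation options: six published HA production strategies,
# three from the natural producer (endogenous) and three recombinant hosts.
# Titers are final broth concentrations; media are initial concentrations.
options:
  - option_id: 1
    source: endogenous
    organism: "Streptococcus equi subsp. zooepidemicus (NJUST01)"
    titer_g_per_L: 6.7
    duration_h: 36.0
    media_g_per_L:
      starch: 20.0
      glucose: 50.0
      peptone: 3.0
      MgSO4: 5.0
      K2HPO4: 1.5
  - option_id: 2
    source: endogenous
    organism: "Streptococcus equi subsp. zooepidemicus (WSH-4)"
    # Biphasic fed-batch/batch schedule collapsed to a single 20 h
    # fermentation at the reported final titer; feed dynamics are not
    # modeled (only titer, duration and recipe enter the economics).
    titer_g_per_L: 6.6
    duration_h: 20.0
    media_g_per_L:
      sucrose: 75.0
      yeast extract: 25.0
      K2SO4: 1.3
      MgSO4-7H2O: 2.0
      Na2HPO4-12H2O: 6.2
      FeSO4-7H2O: 0.005
      ZnCl2: 0.00012
      CuSO4-5H2O: 4.75e-05
  - option_id: 3
    source: endogenous
    organism: "Streptococcus equi subsp. zooepidemicus (ATCC 39920)"
    titer_g_per_L: 5.0
    duration_h: 24.0
    media_g_per_L:
      sucrose: 50.0
      yeast extract: 3.5
      K2HPO4: 2.0
      casein enzyme hydrolysate: 25.0
      NaCl: 1.5
      MgSO4-7H2O: 0.4
  - option_id: 4
    source: recombinant
    # Organism recorded verbatim from the source report.
    organism: "Streptomyces albulus"
    titer_g_per_L: 6.0
    duration_h: 72.0
    media_g_per_L:
      glucose: 50.0
      (NH4)2SO4: 1.0
      Na2HPO4: 1.6
      KH2PO4: 1.4
      MgSO4-7H2O: 0.5
      ZnSO4-7H2O: 0.04
      FeSO4-7H2O: 0.03
  - option_id: 5
    source: recombinant
    organism: "Bacillus subtilis"
    titer_g_per_L: 6.8
    duration_h: 48.0
    media_g_per_L:
      yeast extract: 5.0
      peptone: 10.0
      NaCl: 10.0
  - option_id: 6
    source: recombinant
    organism: "Pichia pastoris"
    titer_g_per_L: 0.76
    duration_h: 48.0
    media_g_per_L:
      glucose: 40.0
      yeast extract: 7.5
      peptone: 10.0
      K2HPO4: 2.5
      MgSO4: 0.5
      NaCl: 5.0
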