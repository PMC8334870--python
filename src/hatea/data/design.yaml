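# Variation design for the sensitivity and simultaneous-variation studies.
multiplier_levels: [0.1, 0.5, 1.0, 2.0, 10.0]
scale_levels_L: [1.0, 10.0, 50.0, 100.0, 250.0, 500.0, 1000.0]
discount_levels: [0.0, 0.2, 0.4, 0.6, 0.8]
yield_levels: [0.2, 0.4, 0.6, 0.8, 1.0]
n_variable_ops: 5
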