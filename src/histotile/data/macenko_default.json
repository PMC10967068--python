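{"alpha": 1.0, "beta": 0.15, "max_concentrations": [1.2399817213587254, 1.0211661987482856], "method": "macenko", "stain_matrix": [[0.6584877010413421, 0.696852630310617, 0.284236449468506], [0.2247144362427706, 0.9395613509680064, 0.25831742084355913]], "version": 1}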