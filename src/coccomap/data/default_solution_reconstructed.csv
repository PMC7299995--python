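# Reconstructed default culture-solution composition (molar ratios to Ca).
# These are NOT measured values: they are back-computed defaults chosen so
# that the control-culture calcite ratios (Sr/Ca 3.7 mmol/mol, Se/Ca 0.047
# mmol/mol) map onto the reported partition coefficients (D_Sr 0.42,
# D_Se 0.048). Override with your own solution table for real data.
element,ratio_to_ca_mmol_per_mol
Sr,8.81
Se,0.98
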