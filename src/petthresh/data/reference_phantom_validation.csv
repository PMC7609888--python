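inner_diameter_mm,volume_cm3,formula_threshold_percent
37,26.51,31.94
22,5.57,30.92
17,2.57,29.92
10,0.52,40.46
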