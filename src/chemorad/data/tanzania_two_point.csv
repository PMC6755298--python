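time_days,diameter_cm
0,2.147
140,0.58
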