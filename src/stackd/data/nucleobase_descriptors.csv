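nucleobase,n_ha,esp_range
A,10,13.1
G,11,24.3
C,8,22.8
T,9,16.1
U,8,17.7
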