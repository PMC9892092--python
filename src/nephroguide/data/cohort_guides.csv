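patient,cost_eur
1,24.84
2,13.94
3,38.07
4,12.13
5,14.58
6,22.23
7,15.58
8,31.28
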