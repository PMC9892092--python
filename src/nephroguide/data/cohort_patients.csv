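patient,age_months,sex,stage,tumor_type
1,100,M,I,regressive
2,4,M,I,regressive
3,7,M,I,stromal
4,76,F,II,stromal
5,50,F,I,mixed
6,30,F,I,regressive
7,80,F,III,regressive
8,50,M,I,mixed
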