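patient_id,n_focus,n_total,included
1,,,0
2,1588,2974,1
3,,,0
4,1414,2397,1
5,1774,2798,1
6,1851,3382,1
7,1697,3544,1
8,2082,3926,1
9,,,0
10,789,3699,1
11,438,492,1
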