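age_low,age_high,mortality_rate
25,30,0.00668
30,35,0.00821
35,40,0.01009
40,45,0.01240
45,50,0.01524
50,55,0.01874
55,60,0.02303
60,65,0.02830
65,70,0.03478
70,75,0.04275
75,80,0.05254
80,85,0.06458
85,90,0.07937
90,95,0.09755
95,,0.11989
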