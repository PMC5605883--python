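age,age_label,weight
0,0-6 days,0.000592670000
1,7-27 days,0.001926190000
2,28-364 days,0.027114760000
3,1-4 years,0.100754310000
4,5-9 years,0.101495150000
5,10-14 years,0.091378570000
6,15-19 years,0.082270370000
7,20-24 years,0.074070030000
8,25-29 years,0.066687060000
9,30-34 years,0.060040000000
10,35-39 years,0.054055480000
11,40-44 years,0.048667480000
12,45-49 years,0.043816520000
13,50-54 years,0.039449090000
14,55-59 years,0.035516980000
15,60-64 years,0.031976810000
16,65-69 years,0.028789510000
17,70-74 years,0.025919900000
18,75-79 years,0.023336320000
19,80-84 years,0.021010260000
20,85-89 years,0.018916050000
21,90-94 years,0.017030590000
22,95 plus,0.005185900000
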