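age,age_label,sle
0,0-6 days,86.6
1,7-27 days,86.55
2,28-364 days,86.06
3,1-4 years,83.615
4,5-9 years,79.194
5,10-14 years,74.361
6,15-19 years,69.611
7,20-24 years,64.945
8,25-29 years,60.363
9,30-34 years,55.864
10,35-39 years,51.448
11,40-44 years,47.116
12,45-49 years,42.868
13,50-54 years,38.703
14,55-59 years,34.621
15,60-64 years,30.623
16,65-69 years,26.709
17,70-74 years,22.878
18,75-79 years,19.13
19,80-84 years,15.466
20,85-89 years,11.886
21,90-94 years,8.389
22,95 plus,4.975
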