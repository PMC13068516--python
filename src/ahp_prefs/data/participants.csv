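# Baseline characteristics of the 26 analyzable respondents of the
# hypertension endpoint-preference survey (transcribed from the published
# study table). vas is the EQ-5D-3L visual analogue scale utility in percent.
id,age,gender,duration_years,scheme,vas
1,72,m,20,mono,60
2,72,m,8,combi,60
3,69,m,18,combi,50
4,64,f,6,combi,75
5,86,f,21,combi,40
6,54,m,7,combi,80
7,67,f,20,combi,80
8,55,f,3,mono,95
9,45,m,1,mono,75
10,67,m,16,combi,70
11,58,m,20,mono,70
12,69,f,15,combi,50
13,53,f,10,mono,80
14,37,f,4,mono,70
15,77,m,22,combi,50
16,46,m,1,combi,65
17,66,m,7,combi,90
18,61,f,5,combi,90
19,71,m,11,combi,50
20,40,m,1,mono,80
21,43,f,2,mono,90
22,52,f,5,combi,80
23,63,f,10,mono,90
24,71,m,9,combi,90
25,69,f,10,combi,70
26,65,f,4,combi,80
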