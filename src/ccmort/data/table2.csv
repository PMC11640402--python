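month,cancer_2001_2010,cancer_2011_2019,cancer_2020_2021,cancer_2001_2021,all_cause_2001_2021
1,48,25,7,80,1256
2,43,30,9,82,1178
3,40,54,7,101,1282
4,53,31,4,88,1265
5,48,30,7,85,1235
6,42,28,3,73,1216
7,56,36,3,95,1323
8,65,34,1,100,1210
9,54,39,2,95,1142
10,57,45,3,105,1370
11,57,28,12,97,1227
12,50,33,8,91,1227
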