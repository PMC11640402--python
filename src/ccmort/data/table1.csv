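group_type,subgroup,cancer_2001_2019,rate_2001_2019,cancer_2020_2021,rate_2020_2021,cancer_2001_2021,rate_2001_2021,all_cause_2001_2021,all_cause_rate_2001_2021
gender,male,574,3.93,36,2.47,610,3.80,8418,52.42
gender,female,452,3.26,30,2.18,482,3.16,6513,42.72
age_group,0-4,397,4.42,20,2.13,417,4.20,12077,121.71
age_group,5-9,318,3.39,26,2.83,344,3.34,1228,11.91
age_group,10-14,311,3.08,20,2.05,331,2.99,1626,14.69
region,HU11,138,3.21,14,3.06,152,3.19,1862,39.65
region,HU12,126,3.27,8,1.80,134,3.12,1630,37.97
region,HU21,87,2.82,5,1.64,92,2.71,1450,42.75
region,HU22,92,3.43,6,2.15,98,3.31,1278,43.14
region,HU23,91,3.50,6,2.52,97,3.41,1395,49.10
region,HU31,159,4.34,9,2.67,168,4.20,2542,63.48
region,HU32,198,4.19,13,2.97,211,4.09,2629,50.92
region,HU33,128,3.54,6,1.79,134,3.39,1952,49.38
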