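eye_id,age_years,naso_temporal_mm,longitudinal_mm
1,2,4.57,3.53
2,2,4.62,3.70
3,2,4.46,3.81
4,2,4.59,3.49
5,2,4.37,3.66
6,2,4.62,3.72
7,2,4.51,3.55
8,2,4.57,3.60
9,3,4.62,3.76
10,3,4.68,3.53
11,3,4.70,3.78
12,3,4.62,3.69
13,3,4.63,3.71
14,3,4.71,3.74
15,3,4.63,3.81
16,3,4.65,3.62
17,4,4.67,3.51
18,4,4.56,3.73
19,4,4.69,3.82
20,4,4.58,3.84
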