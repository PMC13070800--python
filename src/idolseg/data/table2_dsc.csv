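case_id,dsc_fcd_pre,dsc_fcd_post,dsc_idol_post
1,0.45,0.07,0.21
2,0.77,0.57,0.52
3,0.65,0.69,0.78
4,0.46,0.29,0.62
5,0.90,0.75,0.83
6,0.82,0.80,0.85
7,0.61,0.16,0.58
8,0.55,0.42,0.68
9,0.92,0.87,0.90
10,0.81,0.70,0.57
11,0.16,0.14,0.64
12,0.26,0.54,0.57
13,0.83,0.76,0.63
14,0.32,0.64,0.50
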