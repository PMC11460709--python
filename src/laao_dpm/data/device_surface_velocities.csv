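patient,outcome,sys_post_mean,sys_post_sd,sys_pr_mean,sys_pr_sd,dia_post_mean,dia_post_sd,dia_pr_mean,dia_pr_sd,cycle_post_mean,cycle_post_sd,cycle_pr_mean,cycle_pr_sd
1,control,0.08,0.01,0.18,0.13,0.24,0.08,0.27,0.14,0.19,0.1,0.25,0.15
4,control,0.13,0.07,0.26,0.22,0.26,0.08,0.3,0.22,0.22,0.1,0.28,0.21
5,control,0.08,0.0086,,,0.29,0.16,,,0.22,0.2,,
6,control,0.09,0.01,,,0.28,0.12,,,0.21,0.15,,
7,control,0.21,0.15,,,0.20,0.1,,,0.208,0.12,,
8,control,0.15,0.03,,,0.25,0.12,,,0.22,0.11,,
9,control,0.05,0.008,0.13,0.08,0.11,0.09,0.23,0.08,0.1,0.09,0.21,0.099
11,control,0.14,0.017,,,0.31,0.04,,,0.27,0.09,,
13,control,0.05,0.013,0.1,0.026,0.15,0.044,0.26,0.07,0.11,0.059,0.19,0.07
20,control,0.04,0.005,0.08,0.012,0.18,0.08,0.23,0.1,0.11,0.09,0.17,0.11
2,DRT,0.13,0.09,0.08,0.01,0.18,0.08,0.29,0.16,0.16,0.09,0.20,0.14
3,DRT,0.056,0.009,0.07,0.013,0.19,0.18,0.31,0.23,0.15,0.16,0.23,0.2
10,DRT,0.1,0.026,0.06,0.014,0.3,0.2,0.27,0.2,0.26,0.19,0.21,0.19
12,DRT,0.12,0.027,,,0.25,0.14,,,0.2,0.13,,
14,DRT,0.16,0.08,0.12,0.035,0.24,0.1,0.26,0.09,0.21,0.1,0.21,0.1
15,DRT,0.06,0.004,0.19,0.099,0.12,0.1,0.17,0.09,0.1,0.07,0.19,0.11
16,DRT,0.11,0.027,0.37,0.19,0.23,0.14,0.3,0.17,0.17,0.13,0.33,0.18
17,DRT,0.16,0.073,0.1,0.029,0.3,0.077,0.34,0.187,0.25,0.1,0.27,0.19
18,DRT,0.19,0.16,,,0.32,0.12,,,0.28,0.16,,
19,DRT,0.12,0.065,0.17,0.11,0.2,0.15,0.29,0.19,0.17,0.14,0.25,0.18
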