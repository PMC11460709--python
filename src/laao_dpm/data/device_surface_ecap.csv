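patient,outcome,max_post,max_pr,mean_post,sd_post,mean_pr,sd_pr
1,control,0.68,0.51,0.24,0.19,0.2,0.23
4,control,1.24,0.44,0.46,0.9,0.11,0.08
5,control,0.7,,0.26,0.17,,
6,control,1.55,,0.6,0.7,,
7,control,0.39,,0.19,0.08,,
8,control,0.43,,0.14,0.1,,
9,control,1.42,0.63,0.3,0.2,0.24,0.13
11,control,1.02,,0.3,0.4,,
13,control,1.4,1.2,0.7,0.3,0.45,0.43
20,control,2,1.4,1.1,1.3,0.6,0.52
2,DRT,0.99,0.48,0.49,0.4,0.19,0.1
3,DRT,0.55,0.22,0.19,0.13,0.14,0.143
10,DRT,1.26,0.55,0.23,0.2,0.11,0.14
12,DRT,0.48,,0.08,0.1,,
14,DRT,0.8,0.3,0.32,0.12,0.19,0.2
15,DRT,0.76,0.3,0.33,0.2,0.26,0.4
16,DRT,1.08,0.51,0.8,0.6,0.13,0.2
17,DRT,0.3,0.32,0.14,0.11,0.15,0.087
18,DRT,0.2,,0.16,21,,
19,DRT,0.73,0.6,0.24,0.33,0.29,0.2
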