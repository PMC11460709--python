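patient,outcome,low_vel_post,low_vel_pr,recirc_post,recirc_pr,ecap_post,ecap_pr,adhesion_post,adhesion_pr
1,control,NO,NO,YES,NO,NO,NO,YES,NO
4,control,NO,NO,NO,NO,YES,NO,NO,NO
5,control,NO,,YES,,YES,,NO,
6,control,NO,,YES,,YES,,NO,
7,control,NO,,NO,,NO,,NO,
8,control,NO,,NO,,NO,,NO,
9,control,YES,NO,YES,NO,YES,NO,NO,NO
11,control,NO,,NO,,YES,,NO,
13,control,YES,YES,YES,NO,YES,YES,NO,NO
20,control,YES,NO,YES,NO,YES,NO,NO,NO
2,DRT,YES,NO,YES,NO,YES,NO,YES,NO
3,DRT,YES,NO,YES,NO,NO,NO,NO,NO
10,DRT,NO,NO,YES,NO,YES,NO,YES,NO
12,DRT,NO,,NO,,NO,,NO,
14,DRT,NO,NO,NO,NO,YES,NO,YES,NO
15,DRT,YES,NO,YES,NO,YES,NO,YES,NO
16,DRT,YES,NO,YES,NO,YES,NO,NO,NO
17,DRT,NO,NO,NO,NO,NO,NO,YES,YES
18,DRT,NO,,NO,,NO,,NO,
19,DRT,YES,NO,YES,NO,YES,YES,YES,NO
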