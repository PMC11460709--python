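patient,outcome,device_brand,device_class,post_size_mm,pr_size_mm,la_volume_ml,laa_volume_ml,ostium_area_mm2,ostium_perimeter_mm
1,control,Amulet,pacifier,25,28,171,16.7,514.16,37.8
4,control,Watchman,plug,33,27,181,20.5,693.24,43.1
5,control,Watchman,plug,27,,216,18.8,760.49,45.4
6,control,Watchman,plug,27,,94,9.5,566.65,41.7
7,control,Amulet,pacifier,25,,179,11.6,661.83,41.5
8,control,Amulet,pacifier,28,,196,16.3,632.22,41.1
9,control,Watchman,plug,24,30,158,8.9,631.13,42.2
11,control,Amulet,pacifier,22,,127,9,424.91,35.3
13,control,Watchman,plug,24,24,214,9.4,377.08,31.6
20,control,Watchman,plug,24,27,100,6.8,530.48,37.3
2,DRT,ACP,pacifier,22,28,161,20.1,618.647,42.9
3,DRT,ACP,pacifier,16,20,109,3.8,149.48,21.2
10,DRT,Watchman,plug,24,27,89,3.78,417.68,32.9
12,DRT,Amulet,pacifier,25,,212,13.9,660.54,41.3
14,DRT,Amulet,pacifier,25,34,242,17,1266.62,58.4
15,DRT,Watchman,plug,30,33,206,24,736.14,45.2
16,DRT,Watchman,plug,24,27,225,18.4,842.46,47.5
17,DRT,ACP,pacifier,28,26,294,17.4,1073.66,53
18,DRT,ACP,pacifier,28,,213,19,667.43,41.7
19,DRT,Watchman,plug,27,30,220,15.6,740.42,44.3
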