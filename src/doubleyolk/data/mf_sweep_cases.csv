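case,gi_low,gi_medium,gi_high,wi_low,wi_medium,wi_high
1,1.2000,1.3000,1.4000,50.0,70.0,90.0
2,1.2500,1.3500,1.4500,60.0,75.0,85.0
3,1.3000,1.4000,1.5000,65.0,75.0,85.0
4,1.2500,1.3500,1.5000,70.5,72.5,74.5
5,1.2750,1.3750,1.4750,69.0,74.0,79.0
6,1.2750,1.3625,1.4500,69.0,74.0,79.0
7,1.3400,1.3700,1.400,68.0,74.0,82.0
8,1.2750,1.3750,1.4750,70.5,72.5,74.5
9,1.3000,1.4000,1.4500,65.0,75.0,80.0
10,1.3500,1.3800,1.4000,68.0,77.0,80.0
11,1.3250,1.3675,1.4000,67.0,74.0,80.0
12,1.3250,1.3525,1.3850,69.5,74.0,79.5
13,1.3400,1.3500,1.3800,70.0,74.0,82.0
14,1.3400,1.3500,1.3800,69.0,76.0,82.0
15,1.3400,1.3800,1.4000,72.0,76.0,82.0
16,1.3400,1.3800,1.4000,69.0,75.0,81.0
17,1.3000,1.3500,1.3900,70.0,76.0,84.0
18,1.3000,1.3700,1.3800,72.0,73.0,75.0
19,1.3500,1.4000,1.5000,72.0,77.0,90.0
20,1.3000,1.3500,1.4500,65.0,73.0,83.0
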