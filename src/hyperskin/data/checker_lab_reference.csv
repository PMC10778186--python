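patch_id,L_measured,a_measured,b_measured,L_simulated,a_simulated,b_simulated,de2000_reported
1,38.94,24.35,36.89,38.81,24.92,38.23,0.52
2,67.93,32.09,49.08,67.95,32.03,48.94,0.05
3,49.45,0.07,9.87,49.34,-0.66,9.68,1.01
4,42.33,-4.05,39.45,42.59,-3.97,38.03,0.57
5,55.89,16.17,11.32,55.88,16.12,11.33,0.04
6,69.10,-19.39,31.48,69.10,-19.46,31.45,0.05
7,65.32,46.33,82.11,65.37,46.43,81.81,0.14
8,39.09,8.89,-10.49,39.23,9.36,-10.40,0.49
9,55.11,58.96,46.87,55.06,59.03,47.19,0.14
10,31.22,24.81,6.34,31.78,25.36,6.05,0.57
11,71.87,-5.83,76.56,71.87,-5.85,76.51,0.02
12,74.87,34.26,90.13,74.84,34.16,90.25,0.08
13,27.87,11.77,-23.10,27.60,11.34,-23.26,0.46
14,53.97,-27.31,50.50,53.95,-27.22,50.74,0.11
15,45.76,66.20,51.52,45.76,65.96,51.01,0.17
16,83.76,23.22,100.15,83.76,23.26,100.18,0.02
17,54.10,58.28,24.01,54.11,58.30,24.01,0.01
18,48.03,-23.70,-0.08,48.08,-23.35,-0.02,0.19
19,95.47,15.52,46.28,95.48,15.52,46.28,0.00
20,80.98,13.58,40.13,80.95,13.62,40.11,0.04
21,66.39,11.35,34.00,66.52,11.47,34.18,0.14
22,52.19,9.40,28.14,51.90,9.29,28.26,0.31
23,36.45,6.84,21.33,36.46,6.79,21.44,0.09
24,21.36,4.87,14.76,21.05,3.68,15.29,1.55
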