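case_id,d_pre_manual_mm,d_post_manual_mm,d_post_predicted_mm,pct_manual,class_manual,pct_predicted,class_predicted
1,113.5,64.6,80.8,-28.4,SD,-10.5,SD
2,151.8,74.3,80.4,-52.6,PR,-48.7,PR
3,129.3,87.5,84.8,1.9,SD,-1.2,SD
4,100.1,61.8,63.1,-33.7,PR,-32.3,PR
5,178.0,159.0,170.1,-2.9,SD,3.9,SD
6,152.5,138.5,147.7,-8.8,SD,-2.8,SD
7,100.0,91.7,85.5,-5.3,SD,-11.8,SD
8,95.6,81.1,82.0,-7.8,SD,-6.8,SD
9,156.8,144.0,145.0,-0.3,SD,0.4,SD
10,114.3,80.4,109.1,-36.0,PR,-13.2,SD
11,128.9,47.1,48.9,-14.3,SD,-11.0,SD
12,95.9,68.2,116.3,-43.8,PR,-31.9,PR
13,143.1,114.4,126.8,-25.9,SD,-17.9,SD
14,22.6,25.3,26.3,2.1,SD,6.3,SD
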