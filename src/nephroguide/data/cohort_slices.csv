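patient,median_thickness_mm,thickness_min_mm,thickness_max_mm,median_opposite_diff_mm,n_target,n_resulted,avg_dsc,dsc_min,dsc_max,landmarks_matched,landmarks_total
1,5,1,18,2,29,23,0.862,0.760,0.930,1,2
2,6,2,11,1,17,14,0.861,0.812,0.914,3,4
3,5,2,18,2,32,19,0.912,0.899,0.924,4,4
4,5,1,10,1,22,19,0.881,0.799,0.943,2,4
5,5,1,8,0.5,23,20,0.928,0.910,0.940,4,4
6,5,1,9,1.5,24,20,0.925,0.880,0.960,2,2
7,5,3,8,0,20,20,0.735,0.530,0.880,3,5
8,5,2,18,1,31,28,0.958,0.950,0.960,3,4
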