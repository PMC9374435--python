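participant,pathology,enc_max_source,enc_left_pct,enc_max_t,enc_heschl_t,enc_delta_granger_correct,enc_delta_granger_incorrect,maint_max_source,maint_left_pct,maint_max_t,maint_heschl_t,maint_delta_granger_correct,maint_delta_granger_incorrect
1,hippocampal sclerosis,Heschl / Temporal Inferior L,100,17.8,17.8,-0.036,0.087,Frontal Mid Orb / Heschl L,100,10.1,10.1,0.025,-0.037
2,non-lesional,Heschl L,100,19.8,19.8,-0.017,0.016,Temporal Inferior L,96,11.4,10,0.093,0.002
3,focal cortical dysplasia,Temporal Superior L,91,24.2,16.3,-0.060,-0.013,Heschl L,91,14.6,14.6,0.065,0.005
4,unclear etiology,Frontal Inferior L,100,18.3,16.6,-0.006,0.003,Heschl L,100,13.4,13.4,0.035,-0.002
5,brain contusion,Temporal Superior L,100,6.9,5.4,-0.003,-0.002,Heschl L,96,7.6,7.6,0.021,0.048
6,hippocampal sclerosis,Supramarginal L,98,11.1,9.7,-0.049,0.025,Temporal Pole Superior L,93,19.8,17.9,0.039,-0.024
7,xanthoastrozytoma,Lingual R,87,12.9,11.5,-0.059,0.042,Caudate L,85,9.3,8.2,0.042,-0.036
8,focal cortical dysplasia,Caudate L,100,18.8,16.2,-0.040,0.013,Parietal Superior L,100,9.9,8.3,0.017,-0.031
9,gliosis,Cingulum Anterior L,100,12.3,11.2,-0.051,0.012,Parietal Inferior L,100,12.6,11.2,0.050,-0.015
10,hippocampal sclerosis,Heschl L,100,7.9,7.9,-0.070,-0.016,Cingulum Mid L,100,2.7,2.3,0.018,-0.081
11,hippocampal sclerosis,Cingulum Anterior L,100,10.8,6.3,-0.052,-0.011,Cuneus L,86,4.8,4.3,0.020,-0.062
12,hippocampal sclerosis,Temporal Superior L,95,8.1,6.7,-0.022,0.000,Temporal Pole Mid L,100,7.3,4.9,0.012,0.003
13,hippocampal sclerosis,Temporal Superior R,93,10.8,6.9,-0.018,0.019,Parietal Superior R,81,5.6,4.9,0.020,-0.022
14,hippocampal sclerosis,Temporal Superior L,100,16.8,13.3,-0.053,0.022,Heschl L,100,11.8,11.8,0.085,-0.089
15,hippocampal sclerosis,Heschl L,98,9.1,9.1,-0.061,-0.005,Heschl L,100,10.4,10.4,0.069,-0.004
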