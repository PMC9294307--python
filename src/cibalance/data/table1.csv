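participant_id,age_onset_deafness,duration_bilateral_deafness,age_ci1,electrode_array_ci1,age_ci2,electrode_array_ci2,inter_implant_delay,etiology
1,0.63,0.42,1.05,CI24R(CS),9.67,CI513,8.62,Connexin mutation
2,0.00,1.09,1.09,CI24RE(CA),10.33,CI24R(CS),9.24,Unknown
3,0.00,1.73,1.73,CI24(CA),13.36,CI513,11.63,Heredofamilial
4,0.00,1.92,1.92,CI24RE(CA),9.82,CI24(CA),7.91,Connexin mutation
5,0.58,1.45,2.04,CI24(CA),10.05,CI24RE(CA),8.02,Unknown
6,0.00,2.47,2.47,CI24M,15.99,CI513,13.52,Unknown
7,0.00,2.57,2.57,CI24(CA),9.66,CI24RE(CA),7.09,Unknown
8,0.00,2.69,2.69,CI24R(CS),11.52,CI513,8.82,Heredofamilial
9,2.11,1.22,3.34,CI24R(CS),13.25,CI24RE(CA),9.92,Heredofamilial
10,0.00,3.38,3.38,CI24M,16.80,CI24RE(CA),13.42,Heredofamilial
11,0.00,3.39,3.39,Not available,15.99,CI24RE(CA),12.60,Unknown
12,0.00,3.95,3.95,CI24R(CS),12.77,CI513,8.81,Heredofamilial
13,0.00,4.79,4.79,CI24M,16.15,CI513,11.36,Pneumococcal meningitis
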