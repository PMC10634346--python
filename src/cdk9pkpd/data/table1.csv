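subject,indication,cohort,sd_cmax_ug_L,sd_tmax_h,sd_auc_last_ug_h_L,sd_cl_L_h,sd_vss_L,sd_thalf_h,md_cmax_ug_L,md_tmax_h,md_auc_last_ug_h_L,md_thalf_h,response,duration_weeks,exclude_single_sample,exclude_multiple_from_summary
1,Double Hit DLBCL,DH-DLBCL,441,0.583,1350,22.3,74.2,5.68,,,,,Not evaluable,1.14,False,False
2,Double Hit DLBCL,DH-DLBCL,622,0.250,3790,7.44,59.6,6.15,776,0.283,3890,7.03,Progressive disease,3.00,False,False
3,Double Hit DLBCL,DH-DLBCL,716,0.500,2140,14,49.7,2.73,592,0.483,1670,2.53,Complete remission,194,False,True
4,Double Hit DLBCL,DH-DLBCL,561,0.583,3450,,,,524,0.617,3020,4.27,Progressive disease,3.15,False,False
5,Double Hit DLBCL,DH-DLBCL,826,0.533,3410,8.6,51.5,4.45,894,0.583,3190,4.08,Not evaluable,2.14,False,False
6,Double Hit DLBCL,DH-DLBCL,1020,0.500,3220,9.24,42.2,3.32,847,0.617,2490,4.54,Complete remission,122,False,False
7,Double Hit DLBCL,DH-DLBCL,1010,0.517,1980,15.1,42.6,2.48,844,0.567,1660,2.58,Not evaluable,3.29,False,False
8,Double Hit DLBCL,DH-DLBCL,474,0.500,2260,5.87,78.6,9.41,783,0.500,3720,7.21,Not evaluable,3.00,False,False
9,Double Hit DLBCL,DH-DLBCL,448,0.670,3110,9.19,71.7,5.41,410,0.500,2760,5.48,Progressive disease,5.14,True,False
10,Double Hit DLBCL,DH-DLBCL,558,0.500,3370,8.37,71.3,6.02,581,0.500,3090,7.24,Not evaluable,2.14,False,False
11,Triple Hit DLBCL,Other NHL,386,0.500,2030,14.2,97.9,5.22,599,0.500,2080,4.36,Not evaluable,4.00,False,False
12,Transformed follicular lymphoma,Other NHL,517,0.500,3990,6.32,80.3,9.15,699,0.5,3750,8.81,Stable disease,25.6,False,False
13,Burkitt's lymphoma,Other NHL,392,0.670,3230,7.87,98.7,8.93,,,,,Progressive disease,5.14,False,False
14,Mantle cell lymphoma,Other NHL,2150,0.500,4260,6.96,39.2,3.88,,,,,Not evaluable,6.00,False,False
15,DLBCL - (Richters),Other NHL,506,0.500,1930,8.68,82.4,6.78,,,,,Not evaluable,1.14,False,False
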