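severe_vur,age_lt2,male,uti,recurrent_uti,non_ecoli,usg_abnormal,hydronephrosis,utd_p3,dmsa_done,any_scar,multiple_scars,count
0,0,0,0,0,0,1,0,0,1,0,0,57
0,0,0,0,0,0,1,1,1,1,1,1,24
0,0,0,1,0,0,1,1,0,0,,,81
0,0,0,1,0,1,1,1,1,1,1,0,36
0,0,0,1,1,0,0,0,0,1,0,0,2
0,0,1,1,1,0,1,1,1,0,,,3
0,0,1,1,1,1,1,1,0,0,,,145
0,1,0,0,0,0,1,1,0,1,0,0,75
0,1,0,1,0,0,1,0,0,1,0,0,63
0,1,0,1,1,0,0,0,0,1,1,1,113
0,1,0,1,1,0,1,0,0,0,,,90
0,1,0,1,1,0,1,1,1,1,1,1,1
0,1,1,0,0,0,0,0,0,0,,,184
0,1,1,0,0,0,1,1,1,1,1,0,59
0,1,1,1,0,1,0,0,0,1,1,1,9
0,1,1,1,0,1,1,0,0,0,,,1
0,1,1,1,0,1,1,1,1,0,,,15
1,0,0,0,0,0,0,0,0,1,1,1,3
1,0,0,0,0,0,1,1,1,1,1,1,13
1,0,0,1,1,0,1,1,0,1,1,1,1
1,0,1,1,0,0,1,0,0,1,1,1,2
1,0,1,1,0,1,1,1,1,1,0,0,2
1,1,0,1,0,0,1,1,1,1,1,0,5
1,1,0,1,0,1,0,0,0,1,1,1,2
1,1,0,1,0,1,1,1,0,0,,,1
1,1,0,1,1,0,1,1,1,1,1,1,6
1,1,0,1,1,1,1,1,1,1,1,1,1
1,1,1,0,0,0,1,1,1,1,1,1,12
1,1,1,1,0,0,0,0,0,1,1,0,1
1,1,1,1,0,1,1,1,1,0,,,9
1,1,1,1,0,1,1,1,1,1,1,1,1
1,1,1,1,1,0,1,0,0,1,0,0,3
1,1,1,1,1,0,1,1,1,0,,,8
1,1,1,1,1,1,0,0,0,1,0,0,7
1,1,1,1,1,1,1,1,0,1,1,1,9
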