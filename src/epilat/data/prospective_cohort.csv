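patient_id,sex,age_surgery,duration_years,phase1,phase2_3,mts,proc_side,procedure,operated_side,engel_12,engel_24,volumetry,vol_ratio,flair,flair_mean,flair_sd,msa,pet,mmm,mmm_score,dti_uncertainty,dti_connectivity,fmri_connectivity
P01,M,35,11,"F7>F3, T3",Lmt,N,L,resection,left,3A,2C,UR,0.92,R,1.04,0.97,R,_,R,0.833,_,_,_
P02,F,_,55,"F8, F10",_,L,_,none,none,_,_,L,1.99,L,0.90,0.82,L,_,L,1.000,_,_,_
P03,F,_,32,"F3, F1>T3",_,R,R,resection,right,2B,2B,R,0.73,R,1.08,1.30,UL,R,R,0.750,U,U,_
P04,F,32,25,"F3, F7>T3",Lt,N,_,none,none,_,_,U,0.97,L,0.92,0.92,L,L,L,0.750,_,_,_
P05,F,_,59,"F7, T3",_,L,L,resection,left,1A,1A,L,1.31,L,0.70,0.54,L,_,L,1.000,_,_,_
P07,M,_,17,"F7, T1, T3",_,L,L,resection,left,2A,3A,L,1.39,U,1.00,0.96,L,_,L,0.667,_,_,_
P08,F,_,10,"T1, T5, T6",_,N,_,none,none,_,_,U,0.99,R,1.05,1.08,UR,_,R,0.500,L,U,_
P09,F,_,61,"T3, F7",_,L,_,none,none,_,_,L,1.69,L,0.91,0.88,L,_,L,1.000,U,L,_
P10,M,_,24,"T2, F8",_,R,R,resection,right,1A,1A,R,0.84,R,1.06,1.06,R,R,R,1.000,U,R,_
P11,F,19,8,"T1, F7, T3",Lmt,N,L,resection,left,1A,1A,UL,1.08,UL,0.98,1.02,L,_,L,0.667,_,_,_
P12,M,16,6,"F7, T1>T3",Lmt,L,L,resection,left,1A,1A,UL,1.09,L,0.96,0.87,L,L,L,0.875,L,_,_
P14,F,_,4,"F7, T3",_,N,_,none,none,_,_,UL,1.09,L,1.17,1.16,L,_,L,0.833,U,U,_
P15,F,_,59,T3>F7,_,L,L,resection,left,1A,1A,L,2.09,L,0.91,0.82,L,L,L,1.000,L,_,_
P16,M,34,17,"T4, F8",Rtp,N,R,resection,right,1A,1A,R,0.87,R,1.07,1.07,R,L,R,0.750,_,_,_
P17,F,65,49,"T4, F8",Rmt,N,R,resection,right,1A,1A,U,0.97,R,1.06,1.15,U,_,R,0.333,U,U,_
P18,F,_,3,T3>T1,_,L,L,resection,left,1A,2A,R,0.9,L,0.95,0.91,UR,L,L,0.500,U,L,L
P19,M,43,17,T1>T3,Lmt,N,L-RNS,rns,left,_,_,U,0.96,_,_,_,UR,UL,U,_,L,L,_
P20,F,32,5,T2>F8,Rmt,N,R,resection,right,1A,1A,UL,1.1,UR,1.01,0.95,R,U,U,_,U,UL,_
P21,F,44,33,"F7>T1, T2>T4",Lmt,N,B-RNS,rns,bilateral,_,_,U,0.95,UL,0.98,0.84,UR,L,U,_,U,L,_
P22,F,23,1,"T2, T4",Rmt,N,R,resection,right,3A,2B,UL,1.10,U,1.01,1.01,UR,U,U,_,L,U,_
P23,F,33,7,T3>T1,Lt>Rt,N,_,none,none,_,_,UL,1.07,L,0.85,0.82,UR,L,L,0.625,L,R,_
P24,M,53,20,"T1, T3>F7",Ltc,N,L-RNS,resection+rns,left,1B,1B,U,1.00,L,0.91,0.90,UR,L,L,0.500,U,U,_
P25,F,_,2,"T1, T3>F7",_,N,_,none,none,_,_,L,1.14,R,1.03,1.44,F,UR,U,_,_,_,R
P26,F,_,7,"C4-P4, T4-T6",_,N,_,none,none,_,_,U,1.00,R,1.04,0.76,R,_,R,0.667,_,_,R
P27,F,65,64,F7,Lmt>Rtc,L,L,resection,left,1A,1A,L,1.74,_,_,_,L,L,L,1.000,L,U,_
P28,F,41,37,C3-P3,Lf,N,L-RNS,rns,left,_,_,UL,1.07,U,1.01,0.97,R,_,U,_,_,_,_
P29,F,38,33,"T5>F7, T3",Lmt,N,L,resection,left,2B,1B,R,0.66,R,1.13,0.71,R,L,R,0.750,L,L,_
P30,M,58,14,"T2>F8, T4",Rmt,N,R,resection,right,1A,1A,UR,0.90,R,1.13,1.15,R,R,R,0.875,U,R,_
P31,M,_,64,"F8, O2",Rmt,R,R,resection,right,1B,1A,R,0.62,_,_,_,R,R,R,1.000,_,_,_
P32,F,44,24,"F8>T2,T6>O2","Rmt, Rbto",N,R,resection,right,1A,1A,UL,1.06,U,1.00,0.82,R,R,R,0.500,_,U,_
P33,M,73,1,"C4, P4, T6",Rmt,R>L,R,resection,right,3A,3A,R,0.46,UL,0.96,1.07,R,_,R,0.667,_,_,_
P34,M,44,40,"F8, T8","Rstg, Rph",N,R-RNS,rns,right,_,_,UL,1.11,L,0.96,1.11,R,_,U,_,L,F,F
P35,M,50,5,"F7, T1, T2, T8",Lmt>Rmt,N,B-RNS,rns,bilateral,_,_,U,0.98,UL,0.98,1.04,UL,L,L,0.500,_,_,_
P36,F,50,53,"F7>T1,T2,T4",Lmt>Rmt,N,B-RNS,rns,bilateral,_,_,U,0.92,U,1.00,1.09,R,L,U,_,U,L,_
P37,F,47,40,"P8,D2,T7,F7",Lt,N,B-RNS,rns,bilateral,_,_,UL,1.10,_,_,_,L,L,L,0.833,_,_,_
P39,F,_,6,N,_,N,_,none,none,_,_,L,1.23,U,0.99,1.26,L,_,L,0.667,_,L,_
P41,F,28,28,"T7, C3, F8, T8","Lmto, Rp",N,B-RNS,rns,bilateral,_,_,R,0.78,L,0.93,0.86,R,R,R,0.750,_,F,F
P42,F,35,19,"T7, F7",Lbto,N,L,resection,left,3A,3A,UL,1.1,L,0.96,1.05,R,_,U,_,_,_,_
P43,F,32,5,"T2, T8, F8",Rmt>Lmt,L,R-RNS,resection+rns,right,1A,1B,L,1.25,_,_,_,R,_,U,_,R,L,R
P44,F,43,43,Sp2,Rmt,N,R,resection,right,1A,1A,R,0.75,_,_,_,R,_,R,1.000,_,_,_
P45,F,47,10,"T1, F7, T7","Lbt, Lto",N,L-RNS,rns,left,_,_,U,0.95,L,0.96,1.10,UL,L,L,0.625,_,_,_
P46,M,14,10,"C3, C4","Lpc, Lph",N,L-RNS,rns,left,_,_,U,0.96,_,_,_,R,L,U,_,U,UL,_
P47,M,62,10,"F8, T8",_,R,R,resection,right,2B,1C,R,1.39,_,_,_,R,R,R,1.000,R,R,_
P48,M,38,27,"F3, F7, T1>T7",Lmt>Lmf,N,L,resection,left,1A,1A,UL,1.15,U,0.99,1.27,R,_,U,_,UL,L,_
P49,F,65,44,"T2, T9>F8, T8",Lmt>Lmf,N,B-RNS,rns,bilateral,_,_,U,0.96,_,_,_,R,_,R,0.500,_,_,_
P50,M,27,27,P8> P2,"Rbt, Rpo",N,R-RNS,rns,right,_,_,R,0.67,_,_,_,U,L,U,_,UR,L,_
P51,F,18,15,"T3>F8, T2",Rmt,R,R,resection,right,1A,1A,UR,0.81,UL,0.95,1.86,R,R,R,0.625,_,_,_
P52,F,19,12,"T7, T9, P9",Ltc,N,L-RNS,rns,left,_,_,U,0.97,U,1.00,1.01,R,L,U,_,_,_,_
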