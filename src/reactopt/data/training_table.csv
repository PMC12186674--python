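alkene_eq,catalyst_molpct,he_eq,acid_eq,temp_C,time_min,solvent,cost,yield_pct
1.81,1.14,1.56,0.27,28,68,DMF,1.40,26
1.19,2.33,1.81,0.72,43,5.5,DMF,2.05,5
1.81,1.14,1.56,0.27,28,68,DMSO,1.96,8
1.19,2.33,1.81,0.72,43,5.5,DMSO,2.62,2
1.81,1.14,1.24,0.27,28,68,Acetone,1.25,3
1.31,1.50,1.24,0.94,38,38,Acetone,1.42,0
1.69,2.92,1.44,0.49,35,113,NMP,2.38,19
1.19,2.33,1.60,0.72,43,5.5,NMP,2.09,7
1.70,3.05,1.44,0.50,33,25,DCM,2.19,71
1.06,1.45,1.07,0.60,48,53,DCM,1.25,10
1.69,2.92,1.35,0.49,35,113,Cyclohexanone,2.08,0
1.19,2.33,1.35,0.72,43,5.5,Cyclohexanone,1.75,0
1.56,3.05,1.19,0.38,18,98,THFA,2.19,0
1.44,0.55,1.28,0.83,23,23,THFA,0.89,0
1.94,0.85,1.94,0.16,13,83,EA,1.17,0
1.56,0.85,1.19,0.38,18,98,EA,1.01,0
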