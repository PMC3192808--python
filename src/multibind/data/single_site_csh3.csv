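motif,sequence,dg_comp_kcal,kd_comp_uM,dg_expt_kcal,kd_expt_uM
P1,VPPPVPPRRR,-7.5,3.2,-5.29,125
P2,SPPAIPPRQP,-4.9,255,-3.87,1396
P3,SPPLLPPREP,-4.5,501,-3.78,1718
P4,AGPPVPPRQS,-4.3,702,-3.92,1318
RP,GTRRHLPSPP,-5.1,182,,
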