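motif,sequence,dg_comp_kcal,kd_comp_uM,dg_expt_kcal,kd_expt_uM
P1,PPPVPPRRR,-7.1,6.2,-6.02,39
P2,PPAIPPRQP,-7.1,6.2,-5.80,56
P3,PPLLPPREP,-5.1,182,-5.36,117
P4,GPPVPPRQS,-6.0,40,-5.58,82
RP,TRRHLPSPP,-5.2,153,,
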