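n_motif,c_motif,ceff_mM,kd_eff_uM
P2,P1,2.1,3.4
P3,P1,1.6,9.2
RP,P1,0.8,19
P4,P1,0.6,16
P1,P2,1.7,33
P3,P2,2.1,77
RP,P2,1.0,156
P4,P2,0.9,133
P1,P3,1.4,47
P2,P3,1.7,56
RP,P3,1.6,129
P4,P3,1.3,112
P1,RP,0.8,88
P2,RP,1.0,92
P3,RP,1.6,129
P4,RP,1.4,111
P1,P4,0.6,84
P2,P4,0.8,91
P3,P4,1.2,132
RP,P4,1.4,117
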