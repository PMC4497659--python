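variable,mean_IUGR,mean_AGA,sd_IUGR,sd_AGA
GestAge,33.26,36.75,3.49,2.57
PRO,35.39,33.064,22.69,21.56
mRNA_BP1,0.069,0.0,0.22,0.0
mRNA_BP2,0.1,0.02,0.22,0.01
mRNA_IL6,0.25,0.09,0.26,0.07
mRNA_IGF1,0.25,0.09,0.26,0.07
mRNA_IGF2,0.16,0.12,0.22,0.08
PLA_IGF2,163.83,134.16,31.46,27.12
PLATNF,1.94,3.36,1.77,2.06
PLAIL6,62.2,44.38,34.11,21.53
PLA_BP2,110.4,83.44,96.36,73.38
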