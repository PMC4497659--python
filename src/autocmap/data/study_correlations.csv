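,Male,Female,GestAge,PRO,mRNA_BP1,mRNA_BP2,mRNA_IL6,mRNA_IGF1,mRNA_IGF2,PLA_IGF2,PLATNF,PLAIL6,PLA_BP2,AGA,IUGR
Male,1.0,-1.0,0.0,0.15,0.12,0.12,0.03,0.03,-0.04,0.15,0.13,-0.04,0.19,0.04,-0.04
Female,-1.0,1.0,0.0,-0.15,-0.12,-0.12,-0.03,-0.03,0.04,-0.15,-0.13,0.04,-0.19,-0.04,0.04
GestAge,0.0,0.0,1.0,0.2,0.01,-0.01,-0.17,-0.17,-0.3,-0.14,0.13,-0.19,-0.06,0.51,-0.51
PRO,0.15,-0.15,0.2,1.0,0.43,0.46,0.24,0.24,-0.29,0.02,0.03,-0.03,0.18,-0.05,0.05
mRNA_BP1,0.12,-0.12,0.01,0.43,1.0,0.96,0.32,0.32,-0.03,0.03,-0.14,-0.15,-0.14,-0.23,0.23
mRNA_BP2,0.12,-0.12,-0.01,0.46,0.96,1.0,0.44,0.44,0.0,0.0,-0.17,-0.11,-0.2,-0.29,0.29
mRNA_IL6,0.03,-0.03,-0.17,0.24,0.32,0.44,1.0,1.0,-0.11,0.16,-0.19,0.43,-0.21,-0.41,0.41
mRNA_IGF1,0.03,-0.03,-0.17,0.24,0.32,0.44,1.0,1.0,-0.11,0.16,-0.19,0.43,-0.21,-0.41,0.41
mRNA_IGF2,-0.04,0.04,-0.3,-0.29,-0.03,0.0,-0.11,-0.11,1.0,0.01,-0.01,-0.14,-0.2,-0.15,0.15
PLA_IGF2,0.15,-0.15,-0.14,0.02,0.03,0.0,0.16,0.16,0.01,1.0,-0.18,0.37,0.36,-0.46,0.46
PLATNF,0.13,-0.13,0.43,0.03,-0.14,-0.17,-0.19,-0.19,-0.01,-0.18,1.0,0.04,-0.11,0.35,-0.35
PLAIL6,-0.04,0.04,-0.19,-0.03,-0.15,-0.11,0.43,0.43,-0.14,0.37,0.04,1.0,0.1,-0.31,0.31
PLA_BP2,0.19,-0.19,-0.06,0.18,-0.14,-0.2,-0.21,-0.21,-0.2,0.36,-0.11,0.1,1.0,-0.16,0.16
AGA,0.04,-0.04,0.51,-0.05,-0.23,-0.29,-0.41,-0.41,-0.15,-0.46,0.35,-0.31,-0.16,1.0,-1.0
IUGR,-0.04,0.04,-0.51,0.05,0.23,0.29,0.41,0.41,0.15,0.46,-0.35,0.31,0.16,-1.0,1.0
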