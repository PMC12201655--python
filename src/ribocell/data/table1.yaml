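P_AT: 0.9
P_BB: 1.0e-05
P_CB: 0.0001
P_CD: 0.1
P_CF: 0.001
P_FJM: 0.9
P_FLM: 0.002
P_FP: 0.001
P_GD: 0.1
P_GF: 0.002
P_GFR: 0.9
P_GPP: 0.9
P_MC: 0.1
P_MF: 0.1
P_MV: 0.9
P_ND: 0.02
P_NDE: 0.001
P_NF: 0.005
P_NFR: 0.2
P_NP: 5.0e-05
P_NPD: 0.005
P_NPF: 0.002
P_NPFR: 0.3
P_NPP: 0.05
P_NPPP: 0.5
P_PD: 0.1
P_PDM: 0.01
P_PF: 0.02
P_PJM: 0.9
P_PLM: 0.0001
P_RL: 1.0e-06
P_SP: 0.5
P_TL: 0.2
N: 30
T_NPPB: 80000
T_FB: 50000
T_GPB: 50000
F_DE: 1.0
F_DO: 10.0
F_PL: 5.0
F_PP: 20.0
F_PPW: 3.0
F_TR: 100.0
L_AM: 200
L_CDR: 7
L_TMIN: 7
SEQ_GR: UUGAGCG
SEQ_NR: GCACGUA
SEQ_NPR: UCACGAG
SEQ_TR: CUGCUAG
SEQ_CTL: GGCUACU
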