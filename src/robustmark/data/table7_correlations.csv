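dataset,task,biomarker,scale,p,rho,significant,note
NLS,RP,SILTIME,UPDRS-III,0.01,0.49,1,
NLS,RP,SILPERC,UPDRS-III,0.01,0.51,1,
NLS,RP,SILSPRAT,UPDRS-III,0.01,0.51,1,
GermanPD,RP,SPTIME,H&Y,0.008,0.33,1,
GermanPD,RP,SILTIME,H&Y,0.007,0.35,1,
GermanPD,RP,SILSPRAT,H&Y,0.007,0.31,1,
GermanPD,RP,SILDUR,H&Y,0.007,0.32,1,
GermanPD,TDU,RHYSTD,H&Y,<0.001,0.38,1,
CzechPD,RP,INTSTD,UPDRS-III,0.02,-0.60,1,
Neurovoz,TDU,F0STD,UPDRS-III,0.04,-0.43,1,
Neurovoz,TDU,F1STD,UPDRS-III,0.04,0.42,1,
Neurovoz,SS,SILDUR,UPDRS-III,0.02,0.67,1,
ItalianPVS,TDU,SPTIME,UPDRS-III.I,0.02,-0.47,1,
ItalianPVS,TDU,SILTIME,UPDRS-III.I,0.003,0.63,1,
ItalianPVS,TDU,SILPERC,UPDRS-III.I,0.003,0.63,1,
ItalianPVS,TDU,SILSPRAT,UPDRS-III.I,0.003,0.63,1,
ItalianPVS,TDU,SILVAR,UPDRS-III.I,0.048,0.40,1,
ItalianPVS,TDU,RHYSTD,UPDRS-III.I,0.018,0.48,1,
ItalianPVS,RP,RHYSTD,UPDRS-III.I,<0.001,0.67,1,
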