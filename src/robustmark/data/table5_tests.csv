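dataset,task,biomarker,family,n_cn,n_pd,H,p,OB,eta2,auroc,significant,note
NLS,SS,SPTIME,acoustic,33,23,8.65,0.01,down,0.14,0.72,1,
NLS,SS,SILDUR,acoustic,33,23,7.87,0.02,up,0.13,0.72,1,
NLS,SS,SILVAR,acoustic,33,23,7.68,0.02,up,0.12,0.72,1,
NLS,SS,F0STD,acoustic,33,23,4.58,0.048,down,0.07,0.67,1,
NLS,SS,INTSTD,acoustic,33,23,13.36,<0.001,up,0.22,0.79,1,
NLS,RP,SILTIME,acoustic,32,22,5.58,0.03,up,0.09,0.69,1,
NLS,RP,SILPERC,acoustic,32,22,6.72,0.03,up,0.11,0.69,1,
NLS,RP,SILSPRAT,acoustic,32,22,6.72,0.03,up,0.11,0.71,1,
NLS,RP,SILDUR,acoustic,32,22,6.12,0.03,up,0.10,0.71,1,
NLS,RP,SILVAR,acoustic,32,22,5.62,0.03,up,0.09,0.70,1,
NLS,RP,F0STD,acoustic,32,22,5.35,0.03,down,0.08,0.69,1,
NLS,RP,INTSTD,acoustic,32,22,5.17,0.03,up,0.08,0.69,1,
GermanPD,TDU,SILTIME,acoustic,88,88,22.32,<0.001,up,0.12,0.71,1,
GermanPD,TDU,SILPERC,acoustic,88,88,32.27,<0.001,up,0.17,0.75,1,
GermanPD,TDU,SILSPRAT,acoustic,88,88,32.27,<0.001,up,0.17,0.67,1,
GermanPD,TDU,SILDUR,acoustic,88,88,27.63,<0.001,up,0.14,0.73,1,
GermanPD,TDU,F0STD,acoustic,88,88,16.31,<0.001,down,0.09,0.68,1,
GermanPD,TDU,F1STD,acoustic,88,88,7.93,0.007,down,0.04,0.62,1,
GermanPD,RP,F0STD,acoustic,88,88,27.52,<0.001,down,0.14,0.73,1,
GermanPD,RP,INTSTD,acoustic,88,88,18.15,<0.001,down,0.09,0.69,1,
GermanPD,SS,SPTIME,acoustic,88,88,24.90,<0.001,down,0.14,0.72,1,
GermanPD,SS,SILDUR,acoustic,88,88,7.69,0.01,up,0.05,0.62,1,
GermanPD,SS,F0STD,acoustic,88,88,21.61,<0.001,down,0.12,0.70,1,
GermanPD,SS,INTSTD,acoustic,88,88,33.63,<0.001,up,0.20,0.75,1,
Neurovoz,TDU,SPTIME,acoustic,46,43,15.17,<0.001,down,0.16,0.74,1,
Neurovoz,TDU,SILPERC,acoustic,46,43,11.60,0.001,up,0.12,0.71,1,
Neurovoz,TDU,SILSPRAT,acoustic,46,43,11.60,0.001,up,0.12,0.71,1,
Neurovoz,TDU,SILVAR,acoustic,46,43,7.03,0.01,up,0.07,0.62,1,
ItalianPVS,TDU,SPTIME,acoustic,35,28,13.23,<0.001,up,0.20,0.77,1,
ItalianPVS,TDU,SILTIME,acoustic,35,28,14.15,<0.001,up,0.22,0.78,1,
ItalianPVS,TDU,SILPERC,acoustic,35,28,7.72,0.006,up,0.11,0.71,1,
ItalianPVS,TDU,SILSPRAT,acoustic,35,28,7.72,0.006,up,0.11,0.71,1,
ItalianPVS,TDU,SILDUR,acoustic,35,28,22.11,<0.001,up,0.34,0.85,1,
ItalianPVS,TDU,SILVAR,acoustic,35,28,14.47,<0.001,up,0.23,0.78,1,
ItalianPVS,TDU,F0STD,acoustic,35,28,10.56,<0.001,down,0.16,0.74,1,
ItalianPVS,TDU,INTSTD,acoustic,35,28,32.79,<0.001,up,0.52,0.92,1,row typeset as RP but carries the TDU sample sizes; encoded as TDU
ItalianPVS,RP,SILTIME,acoustic,21,26,7.79,0.02,up,0.15,0.74,1,
ItalianPVS,RP,SILPERC,acoustic,21,26,6.81,0.02,up,0.12,0.72,1,
ItalianPVS,RP,SILSPRAT,acoustic,21,26,6.81,0.02,up,0.12,0.72,1,
ItalianPVS,RP,SILDUR,acoustic,21,26,10.85,0.01,up,0.22,0.78,1,
ItalianPVS,RP,SILVAR,acoustic,21,26,5.54,0.03,up,0.11,0.70,1,
ItalianPVS,RP,F0STD,acoustic,21,26,6.37,0.01,down,0.12,0.72,1,arrow typeset up; running text states significantly lower pitch variability on this reading task
ItalianPVS,RP,INTSTD,acoustic,21,26,17.23,<0.001,up,0.36,0.86,1,
CzechPD,RP,SILTIME,acoustic,16,20,9.92,0.005,up,0.12,0.82,1,
CzechPD,RP,SILPERC,acoustic,16,20,9.75,0.002,up,0.25,0.85,1,
CzechPD,RP,SILSPRAT,acoustic,16,20,12.25,0.002,up,0.33,0.85,1,
CzechPD,RP,SILDUR,acoustic,16,20,8.21,0.009,up,0.21,0.79,1,
CzechPD,RP,F0STD,acoustic,16,20,5.92,0.04,down,0.14,0.74,1,
CzechPD,RP,INTSTD,acoustic,16,20,4.69,0.04,down,0.10,0.72,1,
CzechPD,RP,SILVAR,acoustic,16,20,4.69,0.04,up,0.10,0.72,1,arrow typeset down (duplicating the adjacent row); running text states higher pause variability in this cohort
CzechPD,SS,SILTIME,acoustic,16,20,14.44,0.001,up,0.39,0.88,1,
CzechPD,SS,SILPERC,acoustic,16,20,11.33,0.002,up,0.30,0.84,1,
CzechPD,SS,SILSPRAT,acoustic,16,20,11.33,0.002,up,0.30,0.84,1,
CzechPD,SS,SILDUR,acoustic,16,20,11.33,0.002,up,0.30,0.84,1,
CzechPD,SS,F0STD,acoustic,16,20,6.41,0.03,down,0.16,0.75,1,
GITA,RP,F0STD,acoustic,50,50,8.46,0.01,down,0.08,0.67,1,
GITA,TDU,F0STD,acoustic,50,50,7.46,0.009,down,0.06,0.57,1,
GITA,TDU,INTSTD,acoustic,50,50,7.90,0.009,down,0.07,0.57,1,
GITA,TDU,F1STD,acoustic,50,50,5.18,0.02,down,0.04,0.56,1,
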