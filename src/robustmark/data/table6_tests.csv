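dataset,task,biomarker,family,n_cn,n_pd,H,p,OB,eta2,auroc,significant,note
NLS,SS,RHYSTD,cognitive,33,23,5.37,0.02,down,0.08,0.67,1,
NLS,RP,RHYSTD,cognitive,32,22,3.88,0.048,up,0.06,0.65,1,
GermanPD,SS,WORDCNT,linguistic,88,88,16.22,<0.001,down,0.08,0.68,1,
GermanPD,SS,SENTCNT,linguistic,88,88,7.86,0.005,down,0.04,0.62,1,
GermanPD,SS,NOUNCNT,linguistic,88,88,14.11,<0.001,down,0.07,0.66,1,
GermanPD,SS,AUXCNT,linguistic,88,88,11.85,0.001,down,0.06,0.65,1,
GermanPD,SS,NPCNT,linguistic,88,88,9.96,0.003,down,0.05,0.64,1,
GermanPD,SS,PPCNT,linguistic,88,88,13.50,<0.001,down,0.07,0.64,1,
GermanPD,SS,RHYSTD,cognitive,88,88,19.35,<0.001,down,0.10,0.69,1,
Neurovoz,TDU,RHYSTD,cognitive,46,43,15.27,<0.001,down,0.16,0.74,1,
Neurovoz,SS,WORDCNT,linguistic,46,43,10.56,0.01,down,0.11,0.74,1,
Neurovoz,SS,SENTCNT,linguistic,46,43,13.37,0.003,down,0.14,0.83,1,
Neurovoz,SS,NOUNCNT,linguistic,46,43,7.06,0.01,down,0.07,0.74,1,
Neurovoz,SS,VERBCNT,linguistic,46,43,11.22,0.006,down,0.11,0.80,1,
Neurovoz,SS,AUXCNT,linguistic,46,43,7.11,0.01,down,0.07,0.74,1,
Neurovoz,SS,NPCNT,linguistic,46,43,8.84,0.01,down,0.09,0.77,1,
Neurovoz,SS,VPCNT,linguistic,46,43,6.91,0.01,down,0.07,0.74,1,
Neurovoz,SS,RHYSTD,cognitive,46,43,6.01,0.01,down,0.06,0.72,1,
Neurovoz,SS,IU,cognitive,46,43,5.21,0.02,down,0.05,0.70,1,
ItalianPVS,RP,RHYSTD,cognitive,21,26,16.99,<0.001,up,0.35,0.81,1,
ItalianPVS,TDU,RHYSTD,cognitive,21,26,3.91,0.047,up,0.06,0.67,1,sample sizes as printed although other TDU rows use the larger groups
GITA,TDU,RHYSTD,cognitive,50,50,4.07,0.04,down,0.03,0.62,1,
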