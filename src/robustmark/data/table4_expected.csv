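biomarker,task_class,direction,family,note
F0STD,All,down,acoustic,
F1STD,All,down,acoustic,
INTSTD,All,down,acoustic,
SPTIME,SS,down,acoustic,
SPTIME,RP,up,acoustic,
SPTIME,TDU,up,acoustic,reading-like repetition task; treated as the reading direction
SILTIME,All,up,acoustic,
SILPERC,All,up,acoustic,
SILSPRAT,All,up,acoustic,
SILDUR,All,up,acoustic,
SILVAR,All,up,acoustic,
WORDCNT,SS,down,linguistic,
WORDLEN,SS,down,linguistic,
SENTCNT,SS,down,linguistic,
SENTLEN,SS,down,linguistic,
NOUNCNT,SS,down,linguistic,
VERBCNT,SS,down,linguistic,
ADJCNT,SS,down,linguistic,
ADVCNT,SS,down,linguistic,
NUMCNT,SS,down,linguistic,
AUXCNT,SS,down,linguistic,
NPCNT,SS,down,linguistic,
VPCNT,SS,down,linguistic,
PPCNT,SS,down,linguistic,
IU,SS,down,cognitive,
RHYSTD,SS,down,cognitive,
RHYSTD,RP,up,cognitive,
RHYSTD,TDU,up,cognitive,reading-like repetition task; treated as the reading direction
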