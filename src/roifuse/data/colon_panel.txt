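# Colon-specific gene panel (user-replaceable; one HUGO symbol per line)
APC
TP53
KRAS
BRAF
PIK3CA
SMAD4
FBXW7
TCF7L2
CTNNB1
EGFR
ERBB2
MLH1
MSH2
MSH6
PMS2
PTEN
NRAS
POLE
STK11
TTN
ATM
SOX9
ARID1A
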