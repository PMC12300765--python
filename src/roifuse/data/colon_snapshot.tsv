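symbol	pathways	drugs
APC	hsa04310 Wnt signaling pathway;hsa05210 Colorectal cancer
TP53	hsa04115 p53 signaling pathway;hsa05210 Colorectal cancer
KRAS	hsa04010 MAPK signaling pathway;hsa05210 Colorectal cancer	Sotorasib;Adagrasib
BRAF	hsa04010 MAPK signaling pathway;hsa05210 Colorectal cancer	Vemurafenib;Dabrafenib;Encorafenib
PIK3CA	hsa04151 PI3K-Akt signaling pathway;hsa05210 Colorectal cancer	Alpelisib
SMAD4	hsa04350 TGF-beta signaling pathway;hsa05210 Colorectal cancer
FBXW7	hsa04120 Ubiquitin mediated proteolysis
TCF7L2	hsa04310 Wnt signaling pathway
CTNNB1	hsa04310 Wnt signaling pathway;hsa05210 Colorectal cancer
EGFR	hsa04012 ErbB signaling pathway;hsa05210 Colorectal cancer	Cetuximab;Panitumumab
ERBB2	hsa04012 ErbB signaling pathway	Trastuzumab;Pertuzumab;Tucatinib
MLH1	hsa03430 Mismatch repair
MSH2	hsa03430 Mismatch repair
MSH6	hsa03430 Mismatch repair
PMS2	hsa03430 Mismatch repair
PTEN	hsa04151 PI3K-Akt signaling pathway
NRAS	hsa04010 MAPK signaling pathway
POLE	hsa03030 DNA replication
STK11	hsa04150 mTOR signaling pathway
TTN
ATM	hsa04110 Cell cycle
SOX9	hsa04310 Wnt signaling pathway
ARID1A	hsa05225 Chromatin remodeling
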