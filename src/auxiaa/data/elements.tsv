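# Promoter cis-regulatory element library (IUPAC patterns), imported from the
# public PLACE nomenclature; a user-supplied library may replace it.
# element_id	name	pattern
S000270	ARFAT_AuxRE	TGTCTC
S000453	MYB1AT	WAACCA
S000407	MYCATERD1	CATGTG
S000174	MYBCORE	CNGTTR
S000413	ABRELATERD1	ACGTG
S000418	DRECRTCOREAT	RCCGAC
S000439	GAREAT	TAACAAR
S000252	CIACADIANLELHC	CAANNNNATC
S000103	SEF4MOTIFGM7S	RTTTTTR
S000144	EBOXBNNAPA	CANNTG
S000148	SEF3MOTIFGM	AACCCA
S000001	CACGTGMOTIF	CACGTG
SREATMSD	SREATMSD	TTATCC
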