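# Default ALL gene-to-pathway assignments (pathway<TAB>gene); user-overridable.
RAS/RTK	NRAS
RAS/RTK	KRAS
RAS/RTK	PTPN11
RAS/RTK	FLT3
RAS/RTK	NF1
RAS/RTK	ABL1
B-cell development	PAX5
B-cell development	IKZF1
B-cell development	ETV6
B-cell development	ZEB2
B-cell development	RUNX1
B-cell development	TCF3
B-cell development	RAG1
B-cell development	RAG2
B-cell development	EBF1
Chromatin regulation	SETD2
Chromatin regulation	HDAC7
Chromatin regulation	NSD2
Chromatin regulation	CTCF
Chromatin regulation	KMT2A
Chromatin regulation	STAG2
Chromatin regulation	HIST1_CLUSTER
Cytokine signalling	JAK2
Cytokine signalling	IL7R
Cytokine signalling	CRLF2
Gene regulation	CREBBP
Gene regulation	MLLT1
Gene regulation	MLLT3
Gene regulation	AFF1
Gene regulation	BTG1
Gene regulation	ERG
Gene regulation	TCF4
Gene regulation	NCOA6
Signal transduction	TBL1XR1
Signal transduction	TBL1X
Signal transduction	PBX1
Signal transduction	PAG1
Cell cycle regulation	CDKN2A
Cell cycle regulation	CDKN2B
Cell cycle regulation	RB1
Immune regulation	BTLA
Immune regulation	HLA-DRB5
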