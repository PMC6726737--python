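node1	node2	combined_score	channels
MAMLD1	MAML1	0.9	curated
MAMLD1	MAML2	0.9	curated
MAMLD1	MAML3	0.9	curated
MAMLD1	NOTCH1	0.9	curated
MAMLD1	NOTCH2	0.9	curated
NOTCH1	WNT9A	0.9	curated
NOTCH1	WNT9B	0.9	curated
NOTCH1	GLI2	0.9	curated
NOTCH1	GLI3	0.9	curated
NOTCH1	FGF10	0.9	curated
NOTCH1	RET	0.9	curated
NOTCH1	PROP1	0.9	curated
NOTCH1	NRP1	0.9	curated
NOTCH2	WNT9A	0.9	curated
NOTCH2	WNT9B	0.9	curated
NOTCH2	GLI2	0.9	curated
NOTCH2	GLI3	0.9	curated
NOTCH2	FGF10	0.9	curated
NOTCH2	RET	0.9	curated
NOTCH2	PROP1	0.9	curated
NOTCH2	NRP1	0.9	curated
GLI3	EVC	0.9	curated
GLI3	FGF10	0.9	curated
GLI3	GLI2	0.9	curated
GLI3	RIPK4	0.9	curated
GLI3	EYA1	0.9	curated
RET	PIK3R3	0.9	curated
PIK3R3	PTPN11	0.9	curated
PTPN11	RIPK4	0.9	curated
RIPK4	ZBTB16	0.9	curated
RIPK4	CUL4B	0.9	curated
NRP1	FLNA	0.9	curated
EYA1	FRAS1	0.9	curated
EYA1	FREM2	0.9	curated
CYP1A1	HSD3B2	0.9	curated
MYO7A	CDH23	0.9	curated
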