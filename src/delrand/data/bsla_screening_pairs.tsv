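library	pair	label
Lib 1	SE	inactive
Lib 1	AT	inactive
Lib 1	PR	inactive
Lib 1	HL	inactive
Lib 1	VV	inactive
Lib 1	PI	inactive
Lib 1	KG	inactive
Lib 1	MK	inactive
Lib 1	RS	inactive
Lib 1	MG	inactive
Lib 1	TQ	inactive
Lib 1	DI	inactive
Lib 1	TG	inactive
Lib 1	PP	inactive
Lib 1	LW	inactive
Lib 1	QL	inactive
Lib 1	NK	inactive
Lib 1	SC	inactive
Lib 1	AE	inactive
Lib 1	IG	inactive
Lib 1	VY	inactive
Lib 1	TD	inactive
Lib 1	GS	inactive
Lib 2	GY	active
Lib 2	GI	active
Lib 2	RG	active
Lib 2	NL	active
Lib 2	SR	active
Lib 2	QY	inactive
Lib 2	GF	inactive
Lib 2	GR	inactive
Lib 2	GT	inactive
Lib 2	SY	inactive
Lib 2	SL	inactive
Lib 2	TY	inactive
Lib 2	TI	inactive
Lib 2	DW	inactive
Lib 2	CC	inactive
Lib 2	HA	inactive
Lib 2	RW	inactive
Lib 2	EP	inactive
Lib 2	VL	inactive
Lib 2	SP	inactive
Lib 2	RC	inactive
Lib 2	PA	inactive
Lib 2	HT	inactive
Lib 2	LS	inactive
Lib 2	TP	inactive
Lib 3	FP	active
Lib 3	MG	active
Lib 3	FH	active
Lib 3	LP	active
Lib 3	LG	active
Lib 3	ME	active
Lib 3	LM	active
Lib 3	LF	inactive
Lib 3	PP	inactive
Lib 3	HH	inactive
Lib 3	LR	inactive
Lib 3	MW	inactive
Lib 3	DA	inactive
Lib 3	MF	inactive
Lib 3	RV	inactive
Lib 3	WI	inactive
Lib 3	FL	inactive
Lib 3	LV	inactive
Lib 3	EI	inactive
Lib 3	IY	inactive
Lib 3	AV	inactive
Lib 4	KP	inactive
Lib 4	CG	inactive
Lib 4	QA	inactive
Lib 4	IY	inactive
Lib 4	RE	inactive
Lib 4	VN	inactive
Lib 4	LK	inactive
Lib 4	MA	inactive
Lib 4	GS	inactive
Lib 4	SV	inactive
Lib 4	LY	inactive
Lib 4	DL	inactive
Lib 4	LE	inactive
Lib 4	AW	inactive
Lib 4	TR	inactive
Lib 5	LG	active
Lib 5	WG	active
Lib 5	FG	active
Lib 5	NG	active
Lib 5	AG	active
Lib 5	TG	active
Lib 5	DG	active
Lib 5	EG	active
Lib 5	KG	active
Lib 5	SG	active
Lib 5	DG	active
Lib 5	YG	active
Lib 5	HG	active
Lib 5	GG	active
Lib 5	LV	active
Lib 5	AP	active
Lib 5	NA	active
Lib 5	SA	active
Lib 5	FP	active
Lib 5	SP	active
Lib 5	YS	active
Lib 5	GS	active
Lib 5	RC	inactive
Lib 5	WD	inactive
Lib 5	TH	inactive
Lib 5	WF	inactive
Lib 5	TA	inactive
Lib 5	GE	inactive
Lib 5	QA	inactive
Lib 5	CC	inactive
Lib 5	PF	inactive
Lib 5	HV	inactive
Lib 5	SC	inactive
Lib 5	AQ	inactive
Lib 5	TA	inactive
Lib 5	PS	inactive
Lib 5	GF	inactive
Lib 5	PT	inactive
Lib 5	RR	inactive
Lib 5	KT	inactive
Lib 5	PN	inactive
Lib 5	NI	inactive
Lib 6	FI	active
Lib 6	LH	active
Lib 6	YM	active
Lib 6	LY	active
Lib 6	TQ	active
Lib 6	LG	active
Lib 6	PC	active
Lib 6	KK	active
Lib 6	RN	active
Lib 6	LF	inactive
Lib 6	PP	inactive
Lib 6	HH	inactive
Lib 6	LR	inactive
Lib 6	MW	inactive
Lib 6	DA	inactive
Lib 6	MF	inactive
Lib 6	RV	inactive
Lib 6	WI	inactive
Lib 6	FL	inactive
Lib 6	LV	inactive
Lib 6	EI	inactive
Lib 6	IY	inactive
Lib 6	AV	inactive
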