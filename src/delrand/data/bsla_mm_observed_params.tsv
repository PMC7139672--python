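variant	substrate	vmax	vmax_se	km_mM	km_se
WT	pNPB	67.29	4.64	0.406	0.083
WT	pNPO	94.50	16.85	0.730	0.342
WT	pNPD	10.69	0.81	0.042	0.022
WT	pNPP	9.18	0.77	0.078	0.035
P5F3	pNPB	44.86	2.34	0.422	0.084
P5F3	pNPO	229.6	94.0	1.730	1.296
P5F3	pNPD	50.59	4.49	0.064	0.035
P5F3	pNPP	50.50	4.15	0.134	0.048
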