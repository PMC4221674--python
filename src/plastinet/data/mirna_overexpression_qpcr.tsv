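mirna	target_gene	p_control	p_overexpression	reported_effect
mir-286	CG15212	0.498	0.037	+
mir-286	CG4000	0.033	0.064	+
mir-286	dyl	0.241	0.018	+
mir-286	Osi7	0.380	0.006	+
mir-286	Pkcdelta	0.044	0.364	+
mir-286	Vha68-1	0.013	0.348	+
mir-34	CG16857	0.034	0.434	+
mir-34	CG34040	0.046	0.036	-
mir-34	dan	0.204	0.367	-
mir-34	Gbeta76c	0.277	0.010	+
mir-34	prc	0.240	0.410	-
mir-34	prm	0.060	0.441	-
mir-92b	CG31869	0.351	0.008	+
mir-92b	CG8303	0.446	0.026	+
mir-92b	fln	0.378	0.034	+
mir-92b	Tusp	0.075	0.032	+
mir-988	CG15571	0.038	0.226	+
mir-988	CG31086	0.036	0.417	+
mir-988	Ela	0.240	0.139	-
mir-988	vkg	0.143	0.058	-
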