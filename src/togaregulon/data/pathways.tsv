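pathway	abbrev	regulators	transporters	n_transporter_genes	n_enzymes	n_total_genes	n_regulon_genes	in_tmaritima
Central carbohydrate metabolism	CCM			0	18	18	0	True
Arabinose, arabinosides	Ara	AraR	AraEFG	3	6	11	10	True
beta-glucosides	Bgl	BglR	BglEFGKL	5	2	9	9	True
Cellobiose	Cel	CelR	CelEFGKL	5	7	13	13	True
Xyloglucan oligosaccharides	Glo	GloR	GloEFGKL	5	3	9	9	True
Chitobiose, chitin	Chi	ChiR	ChiEFG	3	3	7	7	True
Fructose	Fru	FruR	FruAB	2	2	7	6	False
Galactose, galactosides	Gal	GalR	LtpEFGKL,GanEFG	8	7	16	15	True
Glycerol	Glp	GlpP	GlpABC,GlpF	4	2	7	0	True
Digalacturonate, pectin	Uxa	UxaR	AguEFG	3	15	19	16	True
Glucuronate	Kdg	KdgR		0	1	3	3	True
Xylose, xylan	Xyl	XylR	XylEFK,XloEFGKL,XtpEFGKL,XtpN	14	12	27	27	True
Inositol	Ino	IolR	InoEFGK	4	6	11	6	True
Maltose, maltodextrins	Mal		MalEFG	3	8	15	0	True
Ribose	Rbs	RbsR	RbsABC	3	6	12	12	True
Glucose	Glu	GluR	GluEFK	3	0	4	4	True
Trehalose	Tre	TreR	TreEFG	3	1	5	5	True
Mannose, mannosides	Man	ManR	MtpEFGKL	5	7	13	11	True
Rhamnose, rhamnose oligosaccharides	Rha	RhaR	RtpEFGKL	5	8	14	14	True
Arabitol, mannitol	Pol			0	3	3	0	True
Hypothetical sugar utilization	HSU	UgtR,UctR,UgpR	UgtEFGK,UctMPQ,UgpEFG	10	11	24	20	True
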