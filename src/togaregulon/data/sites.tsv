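tf	site_id	genome	operons	dual_with
XylR	XylR.xylA	Tmar	xylA-op
XylR	XylR.xylR	Tmar	xylR-op
XylR	XylR.xynB	Tmar	xynB-op	KdgR
XylR	XylR.xlo	Tmar	xlo-op	KdgR
XylR	XylR.xynA_xtp	Tmar	xynA-op;xtp-op	KdgR
XylR	XylR.xtpN	Tmar	xtpN-op
KdgR	KdgR.uxaC	Tmar	uxaC-op
KdgR	KdgR.xynB_xlo	Tmar	xynB-op;xlo-op	XylR
KdgR	KdgR.xynA_xtp	Tmar	xynA-op;xtp-op	XylR
UxaR	UxaR.pelA	Tmar	pelA-op
UxaR	UxaR.agu	Tmar	agu-op
UxaR	UxaR.aldH	Tmar	aldH-op
UxaR	UxaR.kdg	Tmar	kdg-op
CelR	CelR.cbpA	Tmar	cbpA-op
CelR	CelR.cel	Tmar	cel-op
CelR	CelR.cel12	Tmar	cel12-op
CelR	CelR.tm0312	Tmar	tm0312-op
CelR	CelR.celQ	Tmar	celQ-op
CelR	CelR.glo	Tmar	gloR-op;glo-op	GloR
GloR	GloR.glo	Tmar	gloR-op;glo-op	CelR
BglR	BglR.bgl	Tmar	bgl-op
ChiR	ChiR.chi	Tmar	chi-op
GalR	GalR.gal	Tmar	gal-op
GalR	GalR.gan	Tmar	gan-op
RhaR	RhaR.rha	Tmar	rha-op
RhaR	RhaR.rhaR	Tmar	rhaR-op
RhaR	RhaR.rtp	Tmar	rtp-op
RbsR	RbsR.rbs	Tmar	rbs-op
GluR	GluR.glu	Tmar	glu-op
GluR	GluR.tre	Tmar	tre-op	TreR
TreR	TreR.treTR	Tmar	treTR-op
TreR	TreR.tre	Tmar	tre-op	GluR
ManR	ManR.man	Tmar	man-op
ManR	ManR.mtp	Tmar	mtp-op
IolR	IolR.ino	Tmar	ino-op
AraR	AraR.abf	Tmar	abf-op
AraR	AraR.ara	Tmar	ara-op;araM-op
UgtR	UgtR.ugt	Tmar	ugt-op
UctR	UctR.uct	Tmar	uct-op
UgpR	UgpR.ugp	Tmar	ugp-op
FruR	FruR.fru	Tnap	fru-op
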