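tf	family	effector	effector_status	motif_width	in_tmaritima
AraR	GntR	arabinose	predicted	17	True
BglR	ROK	cellobiose,glucose	validated	18	True
CelR	LacI	cellobiose	validated	20	True
ChiR	ROK	chitobiose	validated	18	True
FruR	DeoR	fructose	predicted	16	False
GalR	LacI	galactose	predicted	20	True
GloR	LacI	unknown	predicted	20	True
GluR	ROK	glucose	validated	18	True
IolR	ROK	unknown	predicted	18	True
KdgR	IclR	unknown	predicted	19	True
ManR	ROK	mannose	validated	18	True
RbsR	LacI	ribose	predicted	20	True
RhaR	DeoR	rhamnose	predicted	16	True
TreR	ROK	trehalose	validated	18	True
UctR	GntR	unknown	predicted	18	True
UgpR	RpiR	unknown	predicted	18	True
UgtR	LacI	unknown	predicted	20	True
UxaR	GntR	unknown	validated	17	True
XylR	ROK	xylose	validated	18	True
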