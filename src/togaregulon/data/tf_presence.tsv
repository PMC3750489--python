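tf	Tmar	Tnea	Tpet	Tnap	TRQ2	Tlet	Tmel	Tafr	Fnod	Pmob	Kole
AraR	1	1	1	1	1	1	0	0	0	0	0
BglR	1	1	1	1	1	1	0	0	0	0	0
CelR	1	1	1	1	1	1	1	0	0	0	1
ChiR	1	1	1	1	1	1	1	1	0	0	0
FruR	0	0	0	1	1	0	0	0	0	0	0
GalR	1	1	1	1	1	1	1	1	0	0	1
GloR	1	1	0	0	1	0	0	0	0	0	1
GlpP	1	1	1	1	1	1	1	1	0	0	1
GluR	1	1	0	1	1	0	0	0	0	0	0
IolR	1	1	1	1	0	0	0	0	0	0	0
KdgR	1	1	1	1	1	0	0	0	0	0	0
ManR	1	1	1	1	1	0	0	0	0	0	0
RbsR	1	1	1	1	0	1	1	1	0	0	1
RhaR	1	1	1	1	0	0	0	0	0	0	0
TreR	1	1	1	1	1	1	1	1	1	0	1
UctR	1	1	1	1	1	0	0	0	0	0	0
UgpR	1	1	1	1	1	0	0	0	0	0	0
UgtR	1	1	1	1	1	1	1	1	1	0	0
UxaR	1	1	1	1	1	0	0	0	0	0	0
XylR	1	1	1	1	1	1	0	0	0	0	0
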