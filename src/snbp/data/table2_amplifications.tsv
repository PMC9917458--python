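gene	amplification_events
# Independent amplification events per gene, one entry per gene as a
# semicolon-separated list of <count><location-class> tokens.
# Location classes: A = all autosomes combined, X, Y, X/Y = either sex
# chromosome, U = unknown location. "0" = no amplification observed.
CG30356	0
CG31010	1X
CG34269	0
CG42355	0
Mst33A	1Y
ddbt	1X
Mst77F	1Y
Prtl99C	2X
CG30056	0
CG14835	1X
Tpl94D	0
Prot	2A;1X;2Y;4X/Y;1U
tHMG	2X;1U
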