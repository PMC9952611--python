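variable	level	cases	controls	or	or_low	or_high
sex	female	60	3377	1.93	1.31	2.87
sex	male	45	4900	-	-	-
age	<=18	9	632	-	-	-
age	19-64	47	4272	0.77	0.40	1.69
age	>=65	49	3373	1.02	0.52	2.23
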