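label	a	b	c	d	prr	ror	ror_low	ror_high	ic025	chi2	starred	inconsistent
amoxicillin\clavulanic acid	120	73848	77248	64455188	1.36	1.36	1.13	1.62	0.18	10.82	ic	-
piperacillin\tazobactam	113	36094	77255	64492942	2.61	2.61	2.17	3.14	1.11	110.45	prr,ror,ic	ic025
ampicillin\sulbactam	12	5034	77356	64524002	1.99	1.99	1.13	3.50	0.19	4.93	ic	ic025
amoxicillin	81	59895	77287	64469141	1.13	1.13	0.91	1.40	-0.15	1.05	-	ic025
ampicillin	26	6381	77342	64522655	3.39	3.40	1.21	2.32	1.20	41.48	prr,ror,ic	ic025,ror_low,ror_high
piperacillin	6	1767	77362	64527269	2.83	2.83	1.27	6.31	0.41	5.38	prr,ror,ic	ic025
flucloxacillin	20	3913	77348	64525123	4.25	4.26	2.15	6.62	1.45	46.50	prr,ror,ic	ic025,ror_low
cloxacillin	13	1742	77355	64527294	6.19	6.23	3.61	10.74	1.85	51.51	prr,ror,ic	ic025
oxacillin	7	1727	77361	64527309	3.37	3.38	1.61	7.10	0.73	9.44	prr,ror,ic	ic025,chi2
nafcillin	24	1299	77344	64527737	15.15	15.41	10.29	28.08	3.34	303.52	prr,ror,ic	ic025,ror_high
penicillin V	5	5860	77363	64523176	0.71	0.71	0.30	1.71	-1.67	0.33	-	ic025
penicillin G	4	6412	77364	64522624	0.52	0.52	0.20	1.39	-2.23	1.32	-	ic025
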