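label	a	b	c	d	prr	ror	ror_low	ror_high	ic025	chi2	starred	inconsistent
amoxicillin\clavulanic acid	120	73848	311	130124	0.68	0.68	0.55	0.84	-0.67	12.67	-	-
piperacillin\tazobactam	113	36094	318	167878	1.65	1.65	1.33	2.05	0.26	20.85	ic	-
ampicillin\sulbactam	12	5034	419	198938	1.13	1.13	0.64	2.01	-0.64	0.07	-	-
amoxicillin	81	59895	350	144077	0.56	0.56	0.44	0.71	-0.99	22.67	-	ic025
ampicillin	26	6381	405	197591	1.98	1.99	1.34	2.96	0.37	11.01	ic	ic025
piperacillin	6	1767	425	202205	1.61	1.62	0.72	3.62	-0.42	0.84	-	ic025
flucloxacillin	20	3913	411	200059	2.48	2.49	1.59	3.90	0.62	15.48	prr,ror,ic	ic025,chi2
cloxacillin	13	1742	418	202230	3.59	3.61	2.08	6.28	1.03	21.15	prr,ror,ic	ic025,ror_low
oxacillin	7	1727	424	202245	1.93	1.93	0.92	4.09	-0.09	2.24	-	ic025,ror_low
nafcillin	24	1299	407	202673	9.05	9.20	6.07	13.94	2.51	155.08	prr,ror,ic	ic025
penicillin V	5	5860	426	198112	0.40	0.40	0.16	0.96	-2.49	3.90	-	ic025,chi2
penicillin G	4	6412	427	197560	0.29	0.29	0.11	0.77	-3.06	6.23	-	ic025
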