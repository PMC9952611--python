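label	a	b	c	d	prr	ror	ror_low	ror_high	ic025	chi2	starred	inconsistent
hypokalemia	113	36094	77255	64492942	2.61	2.61	2.17	3.14	1.11	110.45	prr,ror,ic	ic025
hyperkalemia	48	36159	227018	64343179	0.38	0.38	0.28	0.50	-1.82	48.94	-	ic025
hyponatremia	33	36174	342483	64227714	0.17	0.17	0.12	0.24	-3.04	131.60	-	ic025,chi2
hypernatremia	35	36172	44850	64525347	1.39	1.39	0.99	1.94	-0.01	3.48	-	ror_low
hypocalcemia	22	36185	155848	64414349	0.25	0.25	0.17	0.38	-2.59	48.29	-	ic025
hypercalcemia	7	36200	99053	64471144	0.13	0.13	0.06	0.26	-4.01	41.62	-	ic025
hypomagnesemia	28	36179	104301	64465896	0.48	0.48	0.33	0.69	-1.60	15.39	-	ic025
hypermagnesemia	1	36206	11599	64558598	0.15	0.15	0.02	1.09	-4.74	3.85	-	ic025
hypophosphatemia	7	36200	54216	64515981	0.23	0.23	0.11	0.48	-3.14	17.26	-	ic025
hyperphosphatemia	10	36197	17537	64552660	1.02	1.02	0.55	1.89	-0.85	0.01	-	ic025,chi2
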