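metabolite	reaction	enzyme	gene	O-BGHEXA	O-GMH	O-XPE	O-AHP	O-GM3	SOP	TYR	O-MHE	O-CHE	O-X3G4R
H2SO3	H2SO3 + 3 NADPH => H2S + 3 NADP + 3 H2O	Sulfite reductase (NADPH)	AO090001000571	-1.74	-2.52	-2.07	-2.24	-2.16	-4.11	-2.5	-3.51	-4.4	-4.61
SLF	SLFe => SLF	Sulfate transporter	AO090003000798	-1.53	-1.52	-	-1.74	-1.56	-4.26	-3.57	-4.12	-3.75	-4.08
UPGIII	SAM + UPGIII => SAH + PRECOR	Uroporphyrin-III C-methyltransferase	AO090020000339	-1.57	-1.82	-1.5	-1.57	-1.37	-2.44	-2.36	-3.18	-2.48	-2.64
PETHM	PE => DAGLY + PETHM	Phospholipase C	AO090103000073	1.26	1.28	1.1	0.95	0.75	1.04	0.91	1.26	0.95	0.74
T3P1	R5P + XUL5P <=> S7P + T3P1	Transketolase	AO090023000345	1.2	1.09	1.04	1.27	-	1.08	0.98	1.33	1.27	-
T3P1	E4P + XUL5P <=> F6P + T3P1	Transketolase	-	-	-	-	-	-	-	-	-	-	-
T3P1	XUL5P + FALD <=> T3P1 + GLYN	Transketolase	-	-	-	-	-	-	-	-	-	-	-
TAUR	TAUR + AKG + O2 => H2S + AMIACE + SUCC + CO2	Alpha-ketoglutarate-dependent taurine dioxygenase	AO090023000531	-1.4	-	-1.69	-1.55	-1.44	-	-1.53	-2.1	-1.86	-
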