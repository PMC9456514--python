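#	Protein 1 Names	Protein 2 Names	xLinkScore	Peptide 1	From	To	aa 1	Peptide 2	From	To	aa 2
1	PAP1/pTac3	PAP2/pTac2	72.00	[KELGAGQRPLPETMIALVR]	131	149	K1	[GQLEKSSAAR]	753	762	K5
2	PAP1/pTac3	PAP2/pTac2	194.61	[KELGAGQRPLPETMIALVR]	131	149	K1	[GQLEKSSAAR]	753	762	K5
3	PAP1/pTac3	PAP2/pTac2	49.10	[ENEDSSSFGSSEAVSALER]	50	68	S15	[GQLEKSSAAR]	753	762	S6
4	MURE	PAP1/pTac3	133.68	[ELKPR]	608	612	K3	[VQKAR]	564	568	K3
5	SaRpoA	PAP5/PTAC12	57.62	[GYSLKMSNNFEDR]	156	168	Y2	[IKRDPLAMR]	365	373	K2
6	PAP5/PTAC12	SaRpoC1	99.25	[KLGRPHPFIDPTK]	208	220	K1	[KNYQNER]	683	689	K1
7	SaRpoC1	SaRpoB	108.78	[IFGPIKSGIBABGNYR]	60	75	Y15	[LTPQVAKESSYAPEDR]	733	748	K7
8	SaRpoC1	SaRpoB	52.00	[FRETLLGKR]	489	497	K8	[SKQGGQR]	969	975	S1
9	PAP6/FLN1; FLN2	PAP5/PTAC12	89.14	[KLELVGSMGEDDDSS}	602	617	K1	[NWSVLKSTPELR]	481	492	K6
10	PAP6/FLN1; FLN2	SaRpoA	121.48	[MLTVQPDLMNDKGYLER]	505	521	Y14	[GYSLKMSNNFEDR]	156	168	K5
11	PAP5/PTAC12	RPS2A; RPS2B	39.00	[APQPAGESSSFPSYGKNPGSR]	128	148	S20	[EVATAIR]	137	143	T4
12	PAP2/pTac2	SPPA	67.62	[GGLFKESEVILSR]	503	515	S7	[GQISDQLKSR]	135	144	K8
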