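# PEP subunit registry, v1
# canonical	role	aliases (semicolon-separated, case-insensitive)
alpha	core	α;rpoA;RpoA;SaRpoA;AtRpoA
beta	core	β;rpoB;RpoB;SaRpoB;AtRpoB
beta_prime	core	β';β′;rpoC1;RpoC1;SaRpoC1;AtRpoC1
beta_double_prime	core	β'';β″;rpoC2;RpoC2;SaRpoC2;AtRpoC2
PAP1	pap	pTAC3;pTac3;PTAC3
PAP2	pap	pTAC2;pTac2;PTAC2
PAP3	pap	pTAC10;PTAC10
PAP4	pap	FSD3
PAP5	pap	pTAC12;PTAC12;HEMERA;HMR
PAP6	pap	FLN1
PAP7	pap	pTAC14;PTAC14
PAP8	pap	pTAC6;PTAC6
PAP9	pap	FSD2
PAP10	pap	TrxZ;TRXz
PAP11	pap	MurE;MURE;MurE-like
PAP12	pap	pTAC7;PTAC7
FLN2	candidate
pTAC18	candidate	PTAC18
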