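protease	P4	P3	P2	P1	P1p	P2p	P3p	P4p	observed
PLG	*	*	*	KR	*!P	*	*	*
PGA3	*	*	*	FLYWME	AFILMVWY!P	*	*	*
CTSD	*	*	*	FLWYM	AFILMVW!P	*	*	*
ELANE	*	*	*	AVSGTI	*	*	*	*
F2	*	*	GP	R	*!P	*	*	*
KLK6	*	*	*	KRY	*!P	*	*	*
KLK11	*	*	*	KR	*!P	*	*	*
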