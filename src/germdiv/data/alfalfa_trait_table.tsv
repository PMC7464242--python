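trait	EGY1	EGY2	AUS2	USA1	USA4	USA7	USA8	USA9
RP	sensitive	sensitive	resistant	sensitive	sensitive	sensitive	sensitive	sensitive
PH	≥70	≥70	<70	≥70	≥70	<70	<70	<70
SN	<4	<4	<4	≥4	≥4	<4	<4	<4
PtL	<20	<20	<20	≥20	<20	<20	<20	<20
PtH	glabrous	hairy	hairy	glabrous	glabrous	glabrous	hairy	glabrous
TlL	<20	≥4	<20	≥4	<20	≥4	<20	<20
TlW	<8	≥8	<8	≥8	<8	≥8	<8	<8
TlW/L	<0.4	≥0.4	<0.4	≥0.4	<0.4	≥0.4	<0.4	<0.4
LtL	≥18	≥18	≥18	<18	<18	≥18	≥18	≥18
LtW	≥5	≥5	≥5	≥5	<5	≥5	≥5	≥5
LlW/L	<0.32	<0.32	≥0.32	≥0.32	<0.32	≥0.32	≥0.32	<0.32
TlA	mucronate	mucronate	mucronate	mucronate	mucronate	mucronate	mucronate	hooked
LS	hairy	leafy	leafy	leafy	leafy	leafy	hairy	leafy
SL	≥9	<9	<9	<9	<9	<9	≥9	<9
PdL	<18	≥18	<18	<18	<18	≥18	≥18	≥18
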