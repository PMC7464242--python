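abbreviation	name	state0	state1	state1_aliases	note
RP	Resistance to pests	sensitive	resistant
PH	Plant height (cm)	<70	≥70
SN	Stem number	<4	≥4
PtL	Petiole length (mm)	<20	≥20
PtH	Petiole hairiness	glabrous	hairy
TlL	Terminal leaflet length (mm)	<20	≥20	≥4	published table prints "≥4" for three cultivars where the high state is ≥20; treated as the high state (transcription anomaly)
TlW	Terminal leaflet width (mm)	<8	≥8
TlW/L	Terminal leaflet width/length	<0.4	≥0.4
LtL	Lateral leaflet length (mm)	<18	≥18
LtW	Lateral leaflet width (mm)	<5	≥5
LlW/L	Lateral leaflet width/length	<0.32	≥0.32
TlA	Terminal leaflet apex shape	mucronate	hooked
LS	Leaf stipule shape	hairy	leafy
SL	Stipule length (mm)	<9	≥9
PdL	Peduncle length (mm)	<18	≥18
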