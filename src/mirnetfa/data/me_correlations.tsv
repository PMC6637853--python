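group	mrna_module	mirna_module	r	p
H-OA	palevioletred3	magenta	-0.7	0.01
H-OA	grey	black	-0.6	0.04
H-OA	lightsteelblue1	turquoise	-0.8	0.00
H-OA	bisque4	turquoise	-0.7	0.00
L-OA	coral1	turquoise	-0.7	0.00
L-OA	mediumpurple2	turquoise	-0.6	0.01
L-OA	darkolivegreen	pink	-0.7	0.00
L-OA	orangered	pink	-0.5	0.04
L-OA	lightcyan1	blue	-0.5	0.05
L-OA	mediumorchid	blue	-0.6	0.01
L-OA	lightcyan1	yellow	-0.6	0.03
L-OA	lightcyan1	green	-0.7	0.00
H-CLA	cyan	turquoise	-0.6	0.03
H-CLA	brown	red	-0.6	0.02
H-CLA	plum2	blue	-0.6	0.03
H-CLA	turquoise	blue	-0.6	0.03
H-CLA	darkred	brown	-0.7	0.00
H-CLA	steelblue	brown	-0.5	0.04
H-CLA	thistle1	black	-0.6	0.02
L-CLA	purple	blue	-0.5	0.04
L-CLA	white	blue	-0.5	0.04
L-CLA	orange	red	-0.5	0.04
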