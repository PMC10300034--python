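# Synthetic toy haplogroup tree for tests and examples.
# Node names follow mtDNA nomenclature but the defining mutations are
# invented; this is NOT phylotree and must not be used on real data.
node	parent	mutations
root	.	.
L3	root	A769G A1018G
L2a	root	A2789T G8206A
N	L3	G8701A C9540T T152C
M	L3	T489C C10400T
M1	M	G6446A T6680C
R	N	T12705C A16189C
R0	R	G73A
HV	R0	T14766C
H	HV	G2706A T7028C
H1	H	G3010A
U	R	A11467G G12308A
U5	U	C16192T A16270G
U6	U	G3348A T16172C
K	U	C152T! G9055A
T	R	G709A G8697A
J	R	C295T T16126C
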