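# Stacking free energies at 37 C, kcal/mol.
# Row = outer (closing) pair 5'X/3'Y, column = inner pair 5'W/3'Z
# for the stacked motif 5'XW3' / 3'YZ5'. Pair order: AU UA CG GC GU UG.
pair	AU	UA	CG	GC	GU	UG
AU	-0.9	-1.1	-2.2	-2.1	-0.6	-1.4
UA	-1.3	-0.9	-2.4	-2.1	-1.0	-1.3
CG	-2.1	-2.1	-3.3	-2.4	-1.4	-2.1
GC	-2.4	-2.2	-3.4	-3.3	-1.5	-2.5
GU	-1.3	-1.4	-2.5	-2.1	-0.5	1.5
UG	-1.0	-0.6	-1.5	-1.4	0.3	-0.5
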