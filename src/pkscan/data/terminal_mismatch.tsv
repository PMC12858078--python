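# Terminal mismatch bonuses for interior-loop closing pairs, kcal/mol.
# Row = closing pair, column = ordered unpaired base pair (XY = X on the
# section1 strand, Y on the section2 strand).
pair	AA	AC	AG	AU	CA	CC	CG	CU	GA	GC	GG	GU	UA	UC	UG	UU
AU	-1.2	-1.0	-1.8	-1.4	-1.0	-0.8	-1.6	-0.9	-2.1	-1.6	-2.0	-1.5	-1.4	-0.9	-1.5	-1.7
UA	-1.1	-0.9	-1.7	-1.3	-0.9	-0.7	-1.5	-0.8	-2.0	-1.5	-1.9	-1.4	-1.3	-0.8	-1.4	-1.6
CG	-1.8	-1.6	-2.4	-2.0	-1.6	-1.4	-2.2	-1.5	-2.7	-2.2	-2.6	-2.1	-2.0	-1.5	-2.1	-2.3
GC	-1.7	-1.5	-2.3	-1.9	-1.5	-1.3	-2.1	-1.4	-2.6	-2.1	-2.5	-2.0	-1.9	-1.4	-2.0	-2.2
GU	-0.8	-0.6	-1.4	-1.0	-0.6	0.1	-1.2	-0.5	-1.7	-1.2	-1.6	-1.1	-1.0	-0.5	-1.1	-1.3
UG	-0.7	-0.5	-1.3	-0.9	-0.5	0.2	-1.1	-0.4	-1.6	-1.1	-1.5	-1.0	-0.9	-0.4	-1.0	-1.2
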