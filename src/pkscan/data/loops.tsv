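# Loop initiation (destabilization) energies, kcal/mol, lengths 1-30.
# hairpin column is informational; the section-pair DP uses bulge/interior only.
length	bulge	interior	hairpin
1	3.9	4.1	4.5
2	4.5	4.1	5.2
3	4.8	4.6	5.5
4	5.0	4.9	5.8
5	5.2	5.2	6.0
6	5.4	5.4	6.2
7	5.5	5.6	6.3
8	5.6	5.8	6.5
9	5.7	5.9	6.6
10	5.8	6.1	6.7
11	5.9	6.2	6.8
12	5.9	6.3	6.8
13	6.0	6.4	6.9
14	6.1	6.5	7.0
15	6.1	6.6	7.0
16	6.2	6.6	7.1
17	6.2	6.7	7.2
18	6.3	6.8	7.2
19	6.3	6.8	7.3
20	6.4	6.9	7.3
21	6.4	7.0	7.4
22	6.4	7.0	7.4
23	6.5	7.1	7.5
24	6.5	7.1	7.5
25	6.5	7.2	7.5
26	6.6	7.2	7.6
27	6.6	7.3	7.6
28	6.6	7.3	7.6
29	6.7	7.4	7.7
30	6.7	7.4	7.7
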