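# loop initiation free energies (kcal/mol) by unpaired-loop size
# hairpin: terminal loop; bulge: one-sided; internal: total unpaired (both sides)
# sizes beyond the tabulated base extrapolate as E(base) + 1.75*RT*ln(n/base), RT=0.6163 (37 C)
size	hairpin	bulge	internal
1	inf	3.80	inf
2	inf	2.80	1.50
3	5.40	3.20	1.60
4	5.60	3.60	1.70
5	5.70	4.00	1.80
6	5.40	4.40	2.00
7	6.00	4.57	2.17
8	5.50	4.71	2.31
9	6.40	4.84	2.44
10	6.51	4.95	2.55
11	6.62	5.05	2.65
12	6.71	5.15	2.75
13	6.80	5.23	2.83
14	6.88	5.31	2.91
15	6.95	5.39	2.99
16	7.02	5.46	3.06
17	7.09	5.52	3.12
18	7.15	5.58	3.18
19	7.21	5.64	3.24
20	7.26	5.70	3.30
21	7.31	5.75	3.35
22	7.36	5.80	3.40
23	7.41	5.85	3.45
24	7.46	5.90	3.50
25	7.50	5.94	3.54
26	7.54	5.98	3.58
27	7.58	6.02	3.62
28	7.62	6.06	3.66
29	7.66	6.10	3.70
30	7.70	6.14	3.74
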