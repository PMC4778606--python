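# Nearest-neighbour helix stacking free energies (kcal/mol, 37 C).
# Row = outer pair (5'i-j3'), column = inner pair (5'(i+1)-(j-1)3').
# Canonical pairs only: Watson-Crick AU/UA/GC/CG plus G:U wobble GU/UG.
# Values follow the widely used Turner-style parameter set, rounded to 0.1.
pair	AU	CG	GC	UA	GU	UG
AU	-0.9	-2.2	-2.1	-1.1	-0.6	-1.4
CG	-2.1	-3.3	-2.4	-2.1	-1.4	-2.1
GC	-2.4	-3.4	-3.3	-2.2	-1.5	-2.5
UA	-1.3	-2.4	-2.1	-0.9	-1.0	-1.3
GU	-1.3	-2.5	-2.1	-1.4	-0.5	1.3
UG	-1.0	-1.5	-1.4	-0.6	0.3	-0.5
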