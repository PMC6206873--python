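# nearest-neighbor RNA duplex stack free energies, table version 1
# units: kcal/mol at 37 C; Watson-Crick stacks from the Turner-2004 set
# key: guide-strand dinucleotide 5'->3' bound to its exact complement;
# a stack containing G:U pairs takes the WC value plus gu_penalty per G:U
param	init	4.1
param	gu_penalty	0.5
stack	AA	-0.93
stack	TT	-0.93
stack	AT	-1.10
stack	TA	-1.33
stack	CT	-2.08
stack	AG	-2.08
stack	CA	-2.11
stack	TG	-2.11
stack	GT	-2.24
stack	AC	-2.24
stack	GA	-2.35
stack	TC	-2.35
stack	CG	-2.36
stack	GG	-3.26
stack	CC	-3.26
stack	GC	-3.42
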