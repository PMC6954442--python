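# Nearest-neighbor parameters (Sugimoto et al. formulation).
# dH in kcal/mol, dS in cal/(mol*K). Dinucleotides keyed by the top strand;
# the reverse complement shares the same stack parameters.
key	dH	dS
AA	-8.0	-21.9
AT	-5.6	-15.2
TA	-6.6	-18.4
CA	-8.2	-21.0
GT	-9.4	-25.5
CT	-6.6	-16.4
GA	-8.8	-23.5
CG	-11.8	-29.0
GC	-10.5	-26.4
GG	-10.9	-28.4
init	0.6	-9.0
init_AT	0.0	0.0
init_GC	0.0	0.0
sym	0.0	-1.4
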