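# Unified nearest-neighbor parameters (SantaLucia & Hicks formulation).
# dH in kcal/mol, dS in cal/(mol*K). Dinucleotides keyed by the top strand;
# the reverse complement shares the same stack parameters.
key	dH	dS
AA	-7.6	-21.3
AT	-7.2	-20.4
TA	-7.2	-21.3
CA	-8.5	-22.7
GT	-8.4	-22.4
CT	-7.8	-21.0
GA	-8.2	-22.2
CG	-10.6	-27.2
GC	-9.8	-24.4
GG	-8.0	-19.9
init	0.2	-5.7
init_AT	2.2	6.9
init_GC	0.0	0.0
sym	0.0	-1.4
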