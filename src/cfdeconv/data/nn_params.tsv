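# Nearest-neighbor duplex parameters for DNA/DNA hybridization.
# step: top strand dinucleotide (5'->3') / bottom strand dinucleotide (3'->5')
# dH in kcal/mol, dS in cal/(mol K).  kind: wc = Watson-Crick stack,
# init_AT / init_GC = duplex initiation at a terminal A-T or G-C pair,
# mm = stack containing one internal single mismatch.
# Matched-pair values follow the unified oligonucleotide parameter set;
# mismatch stacks follow the published internal single-mismatch series
# (G-T, G-A, C-T, A-C and like-with-like pairs).
step	dH	dS	kind
AA/TT	-7.9	-22.2	wc
AT/TA	-7.2	-20.4	wc
TA/AT	-7.2	-21.3	wc
CA/GT	-8.5	-22.7	wc
GT/CA	-8.4	-22.4	wc
CT/GA	-7.8	-21.0	wc
GA/CT	-8.2	-22.2	wc
CG/GC	-10.6	-27.2	wc
GC/CG	-9.8	-24.4	wc
GG/CC	-8.0	-19.9	wc
init_GC	0.1	-2.8	init
init_AT	2.3	4.1	init
AG/TT	1.0	0.9	mm
AT/TG	-2.5	-8.3	mm
CG/GT	-4.1	-11.7	mm
CT/GG	-2.8	-8.0	mm
GG/CT	3.3	10.4	mm
GT/CG	-4.4	-12.3	mm
TG/AT	-0.1	-1.7	mm
TT/AG	-1.3	-5.3	mm
AA/TG	-0.6	-2.3	mm
AG/TA	-0.7	-2.3	mm
CA/GG	-0.7	-2.3	mm
CG/GA	-4.0	-13.2	mm
GA/CG	-0.6	-1.0	mm
GG/CA	0.5	3.2	mm
TA/AG	0.7	0.7	mm
TG/AA	3.0	7.4	mm
AC/TT	0.7	0.2	mm
AT/TC	-1.2	-6.2	mm
CC/GT	-0.8	-4.5	mm
CT/GC	-1.5	-6.1	mm
GC/CT	2.3	5.4	mm
GT/CC	5.2	13.5	mm
TC/AT	1.2	0.7	mm
TT/AC	1.0	0.7	mm
AA/TC	2.3	4.6	mm
AC/TA	5.3	14.6	mm
CA/GC	1.9	3.7	mm
CC/GA	0.6	-0.6	mm
GA/CC	5.2	14.2	mm
GC/CA	-0.7	-3.8	mm
TA/AC	3.4	8.0	mm
TC/AA	7.6	20.2	mm
AA/TA	1.2	1.7	mm
CA/GA	-0.9	-4.2	mm
GA/CA	-2.9	-9.8	mm
TA/AA	4.7	12.9	mm
AC/TC	0.0	-4.4	mm
CC/GC	-1.5	-7.2	mm
GC/CC	3.6	8.9	mm
TC/AC	6.1	16.4	mm
AG/TG	-3.1	-9.5	mm
CG/GG	-4.9	-15.3	mm
GG/CG	-6.0	-15.8	mm
TG/AG	1.6	3.6	mm
AT/TT	-2.7	-10.8	mm
CT/GT	-5.0	-15.8	mm
GT/CT	-2.2	-8.4	mm
TT/AT	0.2	-1.5	mm
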