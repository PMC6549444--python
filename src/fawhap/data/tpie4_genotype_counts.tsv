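# Observed TpiE4 genotype-class specimen counts per African collection.
# source_type male_trap = adult males from pheromone traps (all male, two Z
# chromosomes); larva = field-collected larvae of unknown sex.
# Ca1/Ca2/Ra1 are unambiguous haplotype classes; C-YY, H-CC, H-YY are the
# three heterozygote classes (Ca1/Ca2, Ca1/Ra1, Ca2/Ra1 respectively).
collection	source_type	Ca1	Ca2	Ra1	C-YY	H-CC	H-YY
TOGa	larva	16	17	2	24	8	9
TOGb	male_trap	70	47	3	59	13	9
STP	larva	6	3	0	6	1	2
GHA	larva	16	6	2	7	3	1
CHA	larva	7	1	0	4	3	3
nDRC	larva	12	0	0	9	3	0
sDRC	larva	27	8	2	19	5	1
CAR	larva	12	4	0	6	4	2
BUR	larva	21	2	0	10	4	0
KEN	larva	12	2	1	13	3	8
TAN	larva	35	2	0	13	5	3
ZAM	larva	22	13	0	10	3	1
SAf	larva	34	7	2	23	1	1
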