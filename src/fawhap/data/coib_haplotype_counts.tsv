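# Observed COIB haplotype specimen counts per African collection (13
# collection sets, 11 nations, 2016-2017 surveys). Columns are the six
# mitochondrial haplotypes; one row per collection.
collection	CSa1	CSa2	RSa1	RSa2	RSa3	RSa4
GHA	10	0	25	1	0	0
TOGa	52	1	23	2	0	0
TOGb	211	3	112	13	1	0
STP	13	0	5	0	0	0
CHA	3	0	15	0	0	0
nDRC	11	0	10	0	0	0
sDRC	16	0	46	5	0	0
CAR	8	0	19	1	0	0
BUR	16	0	22	0	0	0
KEN	2	0	42	1	0	1
TAN	5	0	59	1	0	0
ZAM	10	0	40	1	0	0
SAf	8	0	81	0	0	0
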