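# Default African fall armyworm marker panel.
# Backbone sequences are SYNTHETIC stand-ins (seeded, fixed);
# diagnostic sites, haplotype allele vectors and indel features
# follow the published marker definitions.
panel_name: africa-default-v1
segments:
  COIB:
    coordinate_origin: predicted COI translational start
    origin_offset: 890
    expected_length: 603
    reference: GGTCTAGCAGATTAGGCCGGTCCAGCCGGCTCATGCTTCGCGAATCAGACTATTTTAAGATCACGCAAGCGATGTGTAATTATTGTTCTGCGCAACGTTCATTTGGAGATGGTGCGACAATCTAATTCAGGGTCGGTGATGGTCTAAGGTTCACTTTACTCACATTATCAACGAGCATCCATCGGTCAGGAAGCGCACGTAGCCTTACCGTGGCGCTTGCGTGCGATAGGGAGACCGTTAAGCACTATTTAGCAGGTACGCTGATTCTGTCAAGTCGGTTGGTAACGAAGTCGTATCACGGGCTTTATAACGGGTGGACTGTGGGATTTACAGAAGGATGAGAGCCAACATGTGTGACTCTTTGCCTTTCGCTTCGTTTCGCGGGTAACCCTGTGGGATAATTGGTCTATTTACCGAATATTCACTCATCCTCTAGCTTGCGATAGGTGGGCTGCGGGTCATCTTATACAGATGTTGGACGGTATCATGGCTCCTGGCAGCGTTCTATTAGTGGCCACATTATGGAGGCCCGATGCGTCGTTTGAGTCTTAGTCACCAACTTGCCACTGACTCCACTAGTCCATAACGGCGTACGTCGAGGGA
  TpiE4:
    coordinate_origin: 5' start of Tpi exon 4
    origin_offset: 0
    expected_length: 199
    reference: ACGAAAAATACACTGTACACGTGTGGCATGCCAGGTGAGCTTAGTGTGAATGGCAGTTGCTTGTCGTGCTTCGCAGTTTAGCGCATTTTAACAGATGACCAGGCCCTTCACAACTCTATTGAATGTAATGGCGGTGTATCCTAATACGCCGGGCAGTGCATATCCATCGGATTACCATTTACCCTAGTACGCACTTCCG
  TpiI4:
    coordinate_origin: 5' start of Tpi intron 4
    origin_offset: 0
    expected_length: 172
    core_start: 10
    core_end: 171
    reference: TGATTCTCAACTTACTGCTGGGACCGTTAAACCTCTGTGGCCATTTACCGTAGCAGTGCGAGAGACCGGGCCCAATTCATGCCAAGTGTTCTAAGACGACCACTTCATTGACCTTCGTAATCCCGGCAATGATATTTGTCAACATTGAGAGCTAGTTCGGCTAGAGTGATCC
sites:
- label: mCOI1125Y
  segment: COIB
  position: 1125
  alleles:
    C: corn-type
    T: rice-type
- label: mCOI1164D
  segment: COIB
  position: 1164
  alleles:
    T: rice-strain
    A: corn-strain
    G: corn-strain
- label: mCOI1176Y
  segment: COIB
  position: 1176
  alleles:
    C: corn-type
    T: rice-type
- label: mCOI1182Y
  segment: COIB
  position: 1182
  alleles:
    C: corn-type
    T: rice-type
- label: mCOI1197R
  segment: COIB
  position: 1197
  alleles:
    A: corn-type
    G: rice-type
- label: mCOI1216W
  segment: COIB
  position: 1216
  alleles:
    A: corn-type
    T: rice-type
- label: mCOI1287R
  segment: COIB
  position: 1287
  alleles:
    A: h-config-A
    G: h-config-G
- label: gTpi129C
  segment: TpiE4
  position: 129
  alleles:
    T: corn-type
    C: Ra1-variant
- label: gTpi144G
  segment: TpiE4
  position: 144
  alleles:
    A: corn-type
    G: Ra1-variant
- label: gTpi165Y
  segment: TpiE4
  position: 165
  alleles:
    C: corn-type
    T: rice-type
- label: gTpi168Y
  segment: TpiE4
  position: 168
  alleles:
    C: corn-type
    T: rice-type
- label: gTpi180C
  segment: TpiE4
  position: 180
  alleles:
    T: corn-type
    C: Ra1-variant
- label: gTpi183Y
  segment: TpiE4
  position: 183
  alleles:
    C: corn-strain
    T: rice-strain
- label: gTpi192Y
  segment: TpiE4
  position: 192
  alleles:
    C: Ca1-type
    T: Ca2-type
- label: gTpi198Y
  segment: TpiE4
  position: 198
  alleles:
    C: Ca1-type
    T: Ca2-type
- label: gTpiI4[131]R
  segment: TpiI4
  position: 131
  alleles:
    G: consensus
    A: variant
  force_base: G
pair_labels:
  TpiCa1+TpiCa2: C-YY
  TpiCa1+TpiRa1: H-CC
  TpiCa2+TpiRa1: H-YY
haplotypes:
- label: COI-CSa1
  segment: COIB
  strain: corn
  alleles:
    mCOI1125Y: C
    mCOI1164D: G
    mCOI1176Y: C
    mCOI1182Y: C
    mCOI1197R: A
    mCOI1216W: A
    mCOI1287R: G
- label: COI-CSa2
  segment: COIB
  strain: corn
  alleles:
    mCOI1125Y: C
    mCOI1164D: A
    mCOI1176Y: C
    mCOI1182Y: C
    mCOI1197R: A
    mCOI1216W: A
    mCOI1287R: G
- label: COI-RSa1
  segment: COIB
  strain: rice
  alleles:
    mCOI1125Y: T
    mCOI1164D: T
    mCOI1176Y: T
    mCOI1182Y: T
    mCOI1197R: G
    mCOI1216W: T
    mCOI1287R: A
- label: COI-RSa2
  segment: COIB
  strain: rice
  alleles:
    mCOI1125Y: C
    mCOI1164D: T
    mCOI1176Y: T
    mCOI1182Y: T
    mCOI1197R: G
    mCOI1216W: T
    mCOI1287R: A
- label: COI-RSa3
  segment: COIB
  strain: rice
  alleles:
    mCOI1125Y: T
    mCOI1164D: T
    mCOI1176Y: C
    mCOI1182Y: T
    mCOI1197R: G
    mCOI1216W: T
    mCOI1287R: A
- label: COI-RSa4
  segment: COIB
  strain: rice
  alleles:
    mCOI1125Y: T
    mCOI1164D: T
    mCOI1176Y: T
    mCOI1182Y: C
    mCOI1197R: G
    mCOI1216W: T
    mCOI1287R: A
- label: TpiCa1
  segment: TpiE4
  strain: corn
  alleles:
    gTpi129C: T
    gTpi144G: A
    gTpi165Y: C
    gTpi168Y: C
    gTpi180C: T
    gTpi183Y: C
    gTpi192Y: C
    gTpi198Y: C
- label: TpiCa2
  segment: TpiE4
  strain: corn
  alleles:
    gTpi129C: T
    gTpi144G: A
    gTpi165Y: C
    gTpi168Y: C
    gTpi180C: T
    gTpi183Y: C
    gTpi192Y: T
    gTpi198Y: T
- label: TpiRa1
  segment: TpiE4
  strain: rice
  alleles:
    gTpi129C: C
    gTpi144G: G
    gTpi165Y: C
    gTpi168Y: T
    gTpi180C: C
    gTpi183Y: T
    gTpi192Y: C
    gTpi198Y: C
- label: TpiI4Ca1a
  segment: TpiI4
  strain: corn
  exon_link: TpiCa1
  substitutions: {}
- label: TpiI4Ca1b
  segment: TpiI4
  strain: corn
  exon_link: TpiCa1
  substitutions: {}
  indels:
  - kind: insertion
    position: 140
    length: 200
    sequence: CCCGTTGTGTACACCTTGGGGTTGTGTCAAATGGTGTTGTTGAACCTTTACGTTTTCTGTCGGCATGTATCCAGACATCAGAGATTCACTCGTGGCCCTATTCCGGTTTGGAATAACGGTGAGGCTATTATACCCGTTCGGTTTAACGAGGGCCGGCATCAGGTTTCGAGCGCGGAGTGTCAAGCGCAAGCGTACAACAT
- label: TpiI4Ca2a
  segment: TpiI4
  strain: corn
  exon_link: TpiCa2
  substitutions:
    22: A
    47: G
    71: T
    96: G
    120: G
- label: TpiI4Ca2b
  segment: TpiI4
  strain: corn
  exon_link: TpiCa2
  substitutions:
    22: A
    47: G
    71: T
    96: G
    120: G
    55: G
    133: C
- label: TpiI4Ca2c
  segment: TpiI4
  strain: corn
  exon_link: TpiCa2
  substitutions:
    22: A
    47: G
    71: T
    96: G
    120: G
    30: G
    60: A
    88: A
    105: C
    150: G
    160: A
- label: TpiI4Ra1a
  segment: TpiI4
  strain: rice
  exon_link: TpiRa1
  substitutions:
    12: C
    18: T
    25: A
    40: A
    52: G
    66: A
    78: T
    90: C
    102: C
    115: C
    126: A
    138: T
    145: C
    155: A
    163: C
    170: C
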