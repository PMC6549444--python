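"""One-off generator for src/fawhap/data/default_panel.yaml.

Backbone sequences are synthetic (seeded) stand-ins; diagnostic-site
alleles, haplotype configurations and indel features follow the published
marker definitions.
"""

import numpy as np
import yaml

rng = np.random.default_rng(20190605)
BASES = np.array(list("ACGT"))


def rand_seq(n):
    return "".join(rng.choice(BASES, size=n))


TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}

# --- COIB: 603-bp amplicon, ref pos 1 == COI coordinate 891 -----------------
coib_offset = 890
coib = list(rand_seq(603))
coib_sites = {  # site position -> (label, CSa1 allele)
    1125: ("mCOI1125Y", "C"),
    1164: ("mCOI1164D", "G"),
    1176: ("mCOI1176Y", "C"),
    1182: ("mCOI1182Y", "C"),
    1197: ("mCOI1197R", "A"),
    1216: ("mCOI1216W", "A"),
    1287: ("mCOI1287R", "G"),
}
for pos, (_, base) in coib_sites.items():
    coib[pos - coib_offset - 1] = base
coib = "".join(coib)

# --- TpiE4: 199 bp, ref pos 1 == exon-4 coordinate 1 ------------------------
tpie4 = list(rand_seq(199))
tpie4_ca1 = {129: "T", 144: "A", 165: "C", 168: "C", 180: "T", 183: "C",
             192: "C", 198: "C"}
for pos, base in tpie4_ca1.items():
    tpie4[pos - 1] = base
tpie4 = "".join(tpie4)

# --- TpiI4: 172 bp of intron, core 10..171 ----------------------------------
tpii4 = list(rand_seq(172))
tpii4[131 - 1] = "G"  # consensus at the poor-signal site
tpii4 = "".join(tpii4)


def subs(positions, seq, offset=0, mode="ts"):
    """position -> substituted base (transition by default)."""
    out = {}
    for i, p in enumerate(positions):
        ref = seq[p - offset - 1]
        if mode == "mix" and i % 3 == 2:
            out[p] = TRANSVERSION[ref]
        else:
            out[p] = TRANSITION[ref]
    return out


ca2a_pos = [22, 47, 71, 96, 120]
ca2b_pos = ca2a_pos + [55, 133]
ca2c_pos = ca2a_pos + [30, 60, 88, 105, 150, 160]
ra1a_pos = [12, 18, 25, 40, 52, 66, 78, 90, 102, 115, 126, 138, 145, 155,
            163, 170]

insert_200 = rand_seq(200)

doc = {
    "panel_name": "africa-default-v1",
    "segments": {
        "COIB": {
            "coordinate_origin": "predicted COI translational start",
            "origin_offset": coib_offset,
            "expected_length": 603,
            "reference": coib,
        },
        "TpiE4": {
            "coordinate_origin": "5' start of Tpi exon 4",
            "origin_offset": 0,
            "expected_length": 199,
            "reference": tpie4,
        },
        "TpiI4": {
            "coordinate_origin": "5' start of Tpi intron 4",
            "origin_offset": 0,
            "expected_length": 172,
            "core_start": 10,
            "core_end": 171,
            "reference": tpii4,
        },
    },
    "sites": [
        {"label": "mCOI1125Y", "segment": "COIB", "position": 1125,
         "alleles": {"C": "corn-type", "T": "rice-type"}},
        {"label": "mCOI1164D", "segment": "COIB", "position": 1164,
         "alleles": {"T": "rice-strain", "A": "corn-strain",
                     "G": "corn-strain"}},
        {"label": "mCOI1176Y", "segment": "COIB", "position": 1176,
         "alleles": {"C": "corn-type", "T": "rice-type"}},
        {"label": "mCOI1182Y", "segment": "COIB", "position": 1182,
         "alleles": {"C": "corn-type", "T": "rice-type"}},
        {"label": "mCOI1197R", "segment": "COIB", "position": 1197,
         "alleles": {"A": "corn-type", "G": "rice-type"}},
        {"label": "mCOI1216W", "segment": "COIB", "position": 1216,
         "alleles": {"A": "corn-type", "T": "rice-type"}},
        {"label": "mCOI1287R", "segment": "COIB", "position": 1287,
         "alleles": {"A": "h-config-A", "G": "h-config-G"}},
        {"label": "gTpi129C", "segment": "TpiE4", "position": 129,
         "alleles": {"T": "corn-type", "C": "Ra1-variant"}},
        {"label": "gTpi144G", "segment": "TpiE4", "position": 144,
         "alleles": {"A": "corn-type", "G": "Ra1-variant"}},
        {"label": "gTpi165Y", "segment": "TpiE4", "position": 165,
         "alleles": {"C": "corn-type", "T": "rice-type"}},
        {"label": "gTpi168Y", "segment": "TpiE4", "position": 168,
         "alleles": {"C": "corn-type", "T": "rice-type"}},
        {"label": "gTpi180C", "segment": "TpiE4", "position": 180,
         "alleles": {"T": "corn-type", "C": "Ra1-variant"}},
        {"label": "gTpi183Y", "segment": "TpiE4", "position": 183,
         "alleles": {"C": "corn-strain", "T": "rice-strain"}},
        {"label": "gTpi192Y", "segment": "TpiE4", "position": 192,
         "alleles": {"C": "Ca1-type", "T": "Ca2-type"}},
        {"label": "gTpi198Y", "segment": "TpiE4", "position": 198,
         "alleles": {"C": "Ca1-type", "T": "Ca2-type"}},
        {"label": "gTpiI4[131]R", "segment": "TpiI4", "position": 131,
         "alleles": {"G": "consensus", "A": "variant"},
         "force_base": "G"},
    ],
    "pair_labels": {
        "TpiCa1+TpiCa2": "C-YY",
        "TpiCa1+TpiRa1": "H-CC",
        "TpiCa2+TpiRa1": "H-YY",
    },
    "haplotypes": [
        # COIB: CSa1 = h4 (G1164 G1287), CSa2 = h2 (A1164 G1287); RSa2-4
        # each one corn-type state at a single strain-biased site
        {"label": "COI-CSa1", "segment": "COIB", "strain": "corn",
         "alleles": {"mCOI1125Y": "C", "mCOI1164D": "G", "mCOI1176Y": "C",
                     "mCOI1182Y": "C", "mCOI1197R": "A", "mCOI1216W": "A",
                     "mCOI1287R": "G"}},
        {"label": "COI-CSa2", "segment": "COIB", "strain": "corn",
         "alleles": {"mCOI1125Y": "C", "mCOI1164D": "A", "mCOI1176Y": "C",
                     "mCOI1182Y": "C", "mCOI1197R": "A", "mCOI1216W": "A",
                     "mCOI1287R": "G"}},
        {"label": "COI-RSa1", "segment": "COIB", "strain": "rice",
         "alleles": {"mCOI1125Y": "T", "mCOI1164D": "T", "mCOI1176Y": "T",
                     "mCOI1182Y": "T", "mCOI1197R": "G", "mCOI1216W": "T",
                     "mCOI1287R": "A"}},
        {"label": "COI-RSa2", "segment": "COIB", "strain": "rice",
         "alleles": {"mCOI1125Y": "C", "mCOI1164D": "T", "mCOI1176Y": "T",
                     "mCOI1182Y": "T", "mCOI1197R": "G", "mCOI1216W": "T",
                     "mCOI1287R": "A"}},
        {"label": "COI-RSa3", "segment": "COIB", "strain": "rice",
         "alleles": {"mCOI1125Y": "T", "mCOI1164D": "T", "mCOI1176Y": "C",
                     "mCOI1182Y": "T", "mCOI1197R": "G", "mCOI1216W": "T",
                     "mCOI1287R": "A"}},
        {"label": "COI-RSa4", "segment": "COIB", "strain": "rice",
         "alleles": {"mCOI1125Y": "T", "mCOI1164D": "T", "mCOI1176Y": "T",
                     "mCOI1182Y": "C", "mCOI1197R": "G", "mCOI1216W": "T",
                     "mCOI1287R": "A"}},
        # TpiE4
        {"label": "TpiCa1", "segment": "TpiE4", "strain": "corn",
         "alleles": {"gTpi129C": "T", "gTpi144G": "A", "gTpi165Y": "C",
                     "gTpi168Y": "C", "gTpi180C": "T", "gTpi183Y": "C",
                     "gTpi192Y": "C", "gTpi198Y": "C"}},
        {"label": "TpiCa2", "segment": "TpiE4", "strain": "corn",
         "alleles": {"gTpi129C": "T", "gTpi144G": "A", "gTpi165Y": "C",
                     "gTpi168Y": "C", "gTpi180C": "T", "gTpi183Y": "C",
                     "gTpi192Y": "T", "gTpi198Y": "T"}},
        {"label": "TpiRa1", "segment": "TpiE4", "strain": "rice",
         "alleles": {"gTpi129C": "C", "gTpi144G": "G", "gTpi165Y": "C",
                     "gTpi168Y": "T", "gTpi180C": "C", "gTpi183Y": "T",
                     "gTpi192Y": "C", "gTpi198Y": "C"}},
        # TpiI4 (allele differences carried as plain substitutions vs the
        # intron reference, which equals TpiI4Ca1a)
        {"label": "TpiI4Ca1a", "segment": "TpiI4", "strain": "corn",
         "exon_link": "TpiCa1", "substitutions": {}},
        {"label": "TpiI4Ca1b", "segment": "TpiI4", "strain": "corn",
         "exon_link": "TpiCa1", "substitutions": {},
         "indels": [{"kind": "insertion", "position": 140, "length": 200,
                     "sequence": insert_200}]},
        {"label": "TpiI4Ca2a", "segment": "TpiI4", "strain": "corn",
         "exon_link": "TpiCa2", "substitutions": subs(ca2a_pos, tpii4)},
        {"label": "TpiI4Ca2b", "segment": "TpiI4", "strain": "corn",
         "exon_link": "TpiCa2", "substitutions": subs(ca2b_pos, tpii4)},
        {"label": "TpiI4Ca2c", "segment": "TpiI4", "strain": "corn",
         "exon_link": "TpiCa2", "substitutions": subs(ca2c_pos, tpii4)},
        {"label": "TpiI4Ra1a", "segment": "TpiI4", "strain": "rice",
         "exon_link": "TpiRa1",
         "substitutions": subs(ra1a_pos, tpii4, mode="mix")},
    ],
}

with open("src/fawhap/data/default_panel.yaml", "w") as fh:
    fh.write(
        "# Default African fall armyworm marker panel.\n"
        "# Backbone sequences are SYNTHETIC stand-ins (seeded, fixed);\n"
        "# diagnostic sites, haplotype allele vectors and indel features\n"
        "# follow the published marker definitions.\n"
    )
    yaml.safe_dump(doc, fh, sort_keys=False, width=78)
print("wrote default_panel.yaml")
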