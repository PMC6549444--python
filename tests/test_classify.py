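"""Per-sequence classification: strain calls, haplotypes, heterozygotes."""

import itertools

import pytest

from fawhap.classify import (
    assign_coib_haplotype,
    assign_tpie4_genotype,
    assign_tpii4_haplotype,
    call_coi_strain,
    call_tpi_strain,
    classify_specimen,
    coib_h_config,
    species_qc,
)
from fawhap.iupac import compatible, union_code


def edit(panel, segment, seq, site_position, base):
    pos = panel.segments[segment].to_ref_pos(site_position)
    return seq[: pos - 1] + base + seq[pos:]


class TestCoiStrain:
    @pytest.mark.parametrize(
        "base, expected, flagged",
        [
            ("T", "RS", False),  # rice-strain diagnostic
            ("A", "CS", False),
            ("G", "CS", False),
            ("C", "unknown", True),  # C1164 unobserved in the species
            ("Y", "unknown", True),  # ambiguity: failed call
        ],
    )
    def test_mcoi1164_decision_table(self, panel, base, expected, flagged):
        seq = edit(panel, "COIB", panel.haplotype_sequence("COI-CSa1"), 1164, base)
        strain, flags = call_coi_strain(seq, panel)
        assert strain == expected
        assert bool(flags) == flagged


class TestHConfig:
    @pytest.mark.parametrize(
        "b1164, b1287, expected",
        [
            ("A", "A", "h1"),
            ("A", "G", "h2"),
            ("G", "A", "h3"),
            ("G", "G", "h4"),
            ("T", "A", "not-applicable"),  # rice-strain
            ("Y", "G", "failed"),
        ],
    )
    def test_two_site_lookup(self, panel, b1164, b1287, expected):
        seq = panel.haplotype_sequence("COI-CSa1")
        seq = edit(panel, "COIB", seq, 1164, b1164)
        seq = edit(panel, "COIB", seq, 1287, b1287)
        assert coib_h_config(seq, panel) == expected

    def test_h_config_agrees_with_strain_call(self, panel):
        # h1..h4 iff CS; rice sequences are never h-labeled
        for label in ("COI-CSa1", "COI-CSa2", "COI-RSa1", "COI-RSa2"):
            seq = panel.haplotype_sequence(label)
            strain, _ = call_coi_strain(seq, panel)
            h = coib_h_config(seq, panel)
            assert (h in {"h1", "h2", "h3", "h4"}) == (strain == "CS")


class TestCoibHaplotype:
    @pytest.mark.parametrize(
        "label",
        ["COI-CSa1", "COI-CSa2", "COI-RSa1", "COI-RSa2", "COI-RSa3", "COI-RSa4"],
    )
    def test_reference_sequences_match_their_own_labels(self, panel, label):
        res = assign_coib_haplotype(panel.haplotype_sequence(label), panel)
        assert (res.status, res.label) == ("match", label)

    def test_csa2_is_the_h2_variant_of_csa1(self, panel):
        seq = edit(panel, "COIB", panel.haplotype_sequence("COI-CSa1"), 1164, "A")
        res = assign_coib_haplotype(seq, panel)
        assert res.label == "COI-CSa2"
        assert coib_h_config(seq, panel) == "h2"

    def test_novel_vector_distance_matches_panel_scan_oracle(self, panel):
        # flip one strain-biased (non-1164) panel site on a CSa1 background
        seq = edit(panel, "COIB", panel.haplotype_sequence("COI-CSa1"), 1197, "G")
        res = assign_coib_haplotype(seq, panel)
        assert res.status == "novel"
        assert res.label == "COI-CSa3"  # deterministic next free corn index
        # oracle: recompute the minimum vector distance by scanning the panel
        seg = panel.segments["COIB"]
        vector = {
            s.label: seq[seg.to_ref_pos(s.position) - 1]
            for s in panel.sites_for("COIB")
        }
        oracle = min(
            sum(vector[s] != b for s, b in h.allele_vector.items())
            for h in panel.haplotypes_for("COIB")
        )
        assert res.distance == oracle == 1

    def test_ambiguity_at_panel_site_fails(self, panel):
        # mitochondrial DNA is haploid: heterozygous signal is not expected
        seq = edit(panel, "COIB", panel.haplotype_sequence("COI-CSa1"), 1164, "R")
        assert assign_coib_haplotype(seq, panel).status == "failed"

    def test_extend_panel_registers_novel_label(self, panel):
        import copy

        local = copy.deepcopy(panel)
        seq = edit(local, "COIB", local.haplotype_sequence("COI-RSa1"), 1197, "A")
        res = assign_coib_haplotype(seq, local, extend_panel=True)
        assert res.label == "COI-RSa5"
        again = assign_coib_haplotype(seq, local)
        assert (again.status, again.label) == ("match", "COI-RSa5")


class TestSpeciesQC:
    def test_exact_panel_sequence_distance_zero(self, panel):
        assert species_qc(panel.haplotype_sequence("COI-CSa1"), panel) == (True, 0)

    def test_one_substitution_still_passes(self, panel):
        seq = panel.haplotype_sequence("COI-RSa1")
        seq = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
        assert species_qc(seq, panel) == (True, 1)

    def test_five_substitutions_fail_with_bruteforce_distance(self, panel):
        seq = list(panel.haplotype_sequence("COI-CSa1"))
        positions = [30, 60, 90, 120, 150]  # away from diagnostic sites
        for p in positions:
            seq[p] = "A" if seq[p] != "A" else "C"
        seq = "".join(seq)
        passed, dist = species_qc(seq, panel)
        assert not passed
        # oracle: brute-force Hamming against every panel COIB sequence
        oracle = min(
            sum(
                not compatible(a, b)
                for a, b in zip(seq, panel.haplotype_sequence(h.label))
            )
            for h in panel.haplotypes_for("COIB")
        )
        assert dist == oracle == 5


class TestTpiStrain:
    @pytest.mark.parametrize(
        "base, expected",
        [("C", "TpiC"), ("T", "TpiR"), ("Y", "TpiH"), ("W", "unknown")],
    )
    def test_gtpi183_decision_table(self, panel, base, expected):
        seq = edit(panel, "TpiE4", panel.haplotype_sequence("TpiCa1"), 183, base)
        strain, _ = call_tpi_strain(seq, panel)
        assert strain == expected


class TestTpie4Genotype:
    def test_single_haplotypes_called_hemizygous(self, panel):
        for label in ("TpiCa1", "TpiCa2", "TpiRa1"):
            gt = assign_tpie4_genotype(panel.haplotype_sequence(label), panel)
            assert gt.genotype == label.removeprefix("Tpi")
            assert gt.haplotypes == (label,)

    def test_c_yy_pattern_decodes_to_ca1_ca2(self, panel, het_merge):
        seq = het_merge(
            panel.haplotype_sequence("TpiCa1"), panel.haplotype_sequence("TpiCa2")
        )
        seg = panel.segments["TpiE4"]
        assert seq[seg.to_ref_pos(183) - 1] == "C"
        assert seq[seg.to_ref_pos(192) - 1] == "Y"
        assert seq[seg.to_ref_pos(198) - 1] == "Y"
        gt = assign_tpie4_genotype(seq, panel)
        assert gt.genotype == "C-YY"
        assert set(gt.haplotypes) == {"TpiCa1", "TpiCa2"}
        assert gt.strain == "TpiC"

    def test_pair_encode_decode_bijection_exhaustive(self, panel, het_merge):
        # for every unordered pair of panel haplotypes the IUPAC-union
        # consensus decodes back to exactly that pair
        labels = [h.label for h in panel.haplotypes_for("TpiE4")]
        expected_class = {
            frozenset({"TpiCa1", "TpiCa2"}): ("C-YY", "TpiC"),
            frozenset({"TpiCa1", "TpiRa1"}): ("H-CC", "TpiH"),
            frozenset({"TpiCa2", "TpiRa1"}): ("H-YY", "TpiH"),
        }
        for a, b in itertools.combinations(labels, 2):
            seq = het_merge(
                panel.haplotype_sequence(a), panel.haplotype_sequence(b)
            )
            gt = assign_tpie4_genotype(seq, panel)
            assert frozenset(gt.haplotypes) == {a, b}
            cls, strain = expected_class[frozenset({a, b})]
            assert gt.genotype == cls
            assert gt.strain == strain

    def test_vector_matching_nothing_is_ambiguous(self, panel):
        # Y at 183 alone (without Ra1's other variant sites) fits no pair
        seq = edit(panel, "TpiE4", panel.haplotype_sequence("TpiCa1"), 183, "Y")
        gt = assign_tpie4_genotype(seq, panel)
        assert gt.genotype == "ambiguous"
        assert gt.strain == "unknown"

    def test_strain_consistency_with_direct_183_call(self, panel, het_merge):
        # whenever both succeed, genotype-derived strain == direct site call
        seqs = [panel.haplotype_sequence(h) for h in ("TpiCa1", "TpiCa2", "TpiRa1")]
        seqs += [het_merge(a, b) for a, b in itertools.combinations(seqs, 2)]
        for seq in seqs:
            gt = assign_tpie4_genotype(seq, panel)
            direct, _ = call_tpi_strain(seq, panel)
            if gt.strain != "unknown" and direct != "unknown":
                assert gt.strain == direct


class TestTpii4:
    @pytest.mark.parametrize(
        "label",
        ["TpiI4Ca1a", "TpiI4Ca1b", "TpiI4Ca2a", "TpiI4Ca2b", "TpiI4Ca2c",
         "TpiI4Ra1a"],
    )
    def test_reference_intron_haplotypes_roundtrip(self, panel, label):
        res = assign_tpii4_haplotype(panel.haplotype_sequence(label), panel)
        assert res.call == label

    def test_in_core_ambiguity_is_heterozygous(self, panel):
        seq = list(panel.haplotype_sequence("TpiI4Ca1a"))
        seq[50 - 1] = "Y"
        assert assign_tpii4_haplotype("".join(seq), panel).call == "heterozygous"

    def test_poor_signal_site_forced_to_consensus(self, panel):
        # R at gTpiI4[131] alone must not block the call
        seq = list(panel.haplotype_sequence("TpiI4Ca1a"))
        seq[131 - 1] = "R"
        assert assign_tpii4_haplotype("".join(seq), panel).call == "TpiI4Ca1a"

    def test_rule_table_oracle_on_substitution_haplotypes(self, panel):
        # independent rule-by-rule reference: force 131, then exact string
        # comparison of the core window against each indel-free haplotype
        seg = panel.segments["TpiI4"]
        core = slice(seg.core_start - 1, seg.core_end)

        def oracle(seq):
            s = list(seq[core])
            s[131 - seg.core_start] = "G"
            s = "".join(s)
            if any(c not in "ACGT" for c in s):
                return "heterozygous"
            for hap in panel.haplotypes_for("TpiI4"):
                if hap.indel_features:
                    continue
                ref = list(panel.haplotype_sequence(hap.label)[core])
                ref[131 - seg.core_start] = "G"
                if s == "".join(ref):
                    return hap.label
            return "novel"

        for label in ("TpiI4Ca1a", "TpiI4Ca2a", "TpiI4Ca2b", "TpiI4Ca2c",
                      "TpiI4Ra1a"):
            seq = panel.haplotype_sequence(label)
            variants = [
                seq,
                seq[: 131 - 1] + "R" + seq[131:],  # poor-signal site only
                seq[:49] + "Y" + seq[50:],  # true in-core ambiguity
                seq[:49] + ("A" if seq[49] != "A" else "C") + seq[50:],  # novel
            ]
            for v in variants:
                assert assign_tpii4_haplotype(v, panel).call == oracle(v)

    def test_novel_core_substitution_is_novel(self, panel):
        seq = list(panel.haplotype_sequence("TpiI4Ca1a"))
        seq[80 - 1] = "A" if seq[80 - 1] != "A" else "C"
        assert assign_tpii4_haplotype("".join(seq), panel).call == "novel"


class TestSpecimenCall:
    def test_full_specimen_classification_and_determinism(self, panel, het_merge):
        seqs = {
            "COIB": panel.haplotype_sequence("COI-RSa1"),
            "TpiE4": het_merge(
                panel.haplotype_sequence("TpiCa1"),
                panel.haplotype_sequence("TpiRa1"),
            ),
            "TpiI4": het_merge(
                panel.haplotype_sequence("TpiI4Ca1a"),
                panel.haplotype_sequence("TpiI4Ra1a"),
            ),
        }
        call = classify_specimen("S1", seqs, panel, "TOGb", "male_trap")
        assert call.coi_strain == "RS"
        assert call.h_config == "not-applicable"
        assert call.coib_haplotype == "COI-RSa1"
        assert call.tpie4_genotype == "H-CC"
        assert call.tpi_strain == "TpiH"
        assert call.tpii4_call == "heterozygous"
        assert call == classify_specimen("S1", seqs, panel, "TOGb", "male_trap")

    def test_missing_markers_leave_failed_fields(self, panel):
        call = classify_specimen(
            "S2", {"COIB": panel.haplotype_sequence("COI-CSa1")}, panel
        )
        assert call.coi_strain == "CS"
        assert call.tpie4_genotype == "failed"
        assert call.tpi_strain == "unknown"

    def test_tpi_strain_iff_genotype_class(self, panel, het_merge):
        # invariant: TpiH iff H-*, TpiC iff {Ca1, Ca2, C-YY}, TpiR iff Ra1
        cases = {
            "Ca1": "TpiC", "Ca2": "TpiC", "Ra1": "TpiR",
            "C-YY": "TpiC", "H-CC": "TpiH", "H-YY": "TpiH",
        }
        pair_seq = {
            "Ca1": ("TpiCa1",), "Ca2": ("TpiCa2",), "Ra1": ("TpiRa1",),
            "C-YY": ("TpiCa1", "TpiCa2"),
            "H-CC": ("TpiCa1", "TpiRa1"),
            "H-YY": ("TpiCa2", "TpiRa1"),
        }
        for cls, labels in pair_seq.items():
            seqs = [panel.haplotype_sequence(x) for x in labels]
            seq = seqs[0] if len(seqs) == 1 else het_merge(*seqs)
            call = classify_specimen("S", {"TpiE4": seq}, panel)
            assert call.tpie4_genotype == cls
            assert call.tpi_strain == cases[cls]
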