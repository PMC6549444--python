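"""Per-sequence classification against the marker panel.

Implements the complete per-specimen genotyping scheme:

* COI strain from the diagnostic site mCOI1164D (T = rice-strain RS;
  A or G = corn-strain CS; C has not been observed in the species),
* the two-site h1-h4 corn-strain configuration (mCOI1164D x mCOI1287R),
* exact COIB haplotype assignment with deterministic auto-labels for
  novel mitochondrial variants,
* species QC (a sequence must sit within one substitution of a panel
  COIB haplotype to count as *S. frugiperda*),
* TpiE4 strain (gTpi183Y: C = TpiC, T = TpiR, Y = heterozygote TpiH) and
  full TpiE4 genotype including IUPAC-union decoding of the male
  heterozygote classes (Tpi is Z-linked, so only males can be
  heterozygous),
* TpiI4 intron haplotype assignment with the poor-signal site forced to
  its consensus base and any remaining in-core ambiguity or incompatible
  indel evidence reported as heterozygous.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .align import Anchoring, UnalignableSequenceError, anchor_to_reference
from .iupac import compatible, is_unambiguous, union_code
from .panel import MarkerPanel, ReferenceHaplotype

H_CONFIG = {
    ("A", "A"): "h1",
    ("A", "G"): "h2",
    ("G", "A"): "h3",
    ("G", "G"): "h4",
}

# slop allowed when matching observed insertions against a haplotype's
# declared indel feature (alignment placement at repeat boundaries is not
# unique; lengths can wobble by a few bases)
INDEL_POS_TOL = 5
INDEL_LEN_TOL = 10


def _anchor(seq, panel: MarkerPanel, segment_name: str) -> Anchoring:
    if isinstance(seq, Anchoring):
        if seq.segment != segment_name:
            raise ValueError(
                f"anchoring is for segment {seq.segment}, expected {segment_name}"
            )
        return seq
    return anchor_to_reference(seq, panel.segments[segment_name])


def _short(label: str) -> str:
    """Reporting form of a TpiE4 haplotype label (TpiCa1 -> Ca1)."""
    return label[3:] if label.startswith("Tpi") else label


# ---------------------------------------------------------------------------
# COIB


def call_coi_strain(seq, panel: MarkerPanel) -> tuple[str, list[str]]:
    """COI strain from mCOI1164D.  Returns (strain, qc_flags).

    T -> "RS"; A or G -> "CS"; C (unobserved in the species) -> "unknown"
    with a flag; unmapped or ambiguous site -> "unknown" with a
    failed-call flag.
    """
    try:
        anch = _anchor(seq, panel, "COIB")
    except (UnalignableSequenceError, ValueError) as exc:
        return "unknown", [f"coi-anchor-failed: {exc}"]
    seg = panel.segments["COIB"]
    base = anch.site_base(seg, panel.sites["mCOI1164D"].position)
    if base is None:
        return "unknown", ["coi-site-unmapped"]
    if not is_unambiguous(base):
        return "unknown", ["coi-site-ambiguous"]
    if base == "T":
        return "RS", []
    if base in ("A", "G"):
        return "CS", []
    return "unknown", ["coi-unexpected-allele-C1164"]


def coib_h_config(seq, panel: MarkerPanel) -> str:
    """Two-site h-configuration of a corn-strain COIB sequence.

    Returns "h1".."h4" for CS sequences, "not-applicable" for rice-strain
    (T at 1164) and "failed" when either site is unmapped or ambiguous.
    """
    try:
        anch = _anchor(seq, panel, "COIB")
    except (UnalignableSequenceError, ValueError):
        return "failed"
    seg = panel.segments["COIB"]
    b1164 = anch.site_base(seg, panel.sites["mCOI1164D"].position)
    b1287 = anch.site_base(seg, panel.sites["mCOI1287R"].position)
    if b1164 is None or b1287 is None:
        return "failed"
    if not (is_unambiguous(b1164) and is_unambiguous(b1287)):
        return "failed"
    if b1164 == "T":
        return "not-applicable"
    return H_CONFIG.get((b1164, b1287), "failed")


@dataclass
class CoibAssignment:
    """Result of exact COIB haplotype matching."""

    label: str  # panel label, auto-generated novel label, or "failed"
    status: str  # "match" | "novel" | "failed"
    distance: int = 0  # substitutions to the nearest panel haplotype
    nearest: str | None = None
    mismatched_sites: tuple[str, ...] = ()
    flags: list[str] = field(default_factory=list)


def _next_auto_label(panel: MarkerPanel, prefix: str, run_suffix: str) -> str:
    pat = re.compile(rf"COI-{re.escape(prefix)}(\d+)")
    taken = [
        int(m.group(1))
        for h in panel.haplotypes_for("COIB")
        if (m := pat.fullmatch(h.label))
    ]
    return f"COI-{prefix}{max(taken, default=0) + 1}{run_suffix}"


def assign_coib_haplotype(
    seq,
    panel: MarkerPanel,
    extend_panel: bool = False,
    run_suffix: str = "",
) -> CoibAssignment:
    """Match the COIB diagnostic-site allele vector to the panel.

    Mitochondrial sequences are haploid, so any IUPAC ambiguity at a panel
    site is a failed call.  A vector matching no panel entry is reported
    as novel with a deterministic next-index label (CSa_n / RSa_n by
    strain); with ``extend_panel`` the panel is updated in place.
    """
    try:
        anch = _anchor(seq, panel, "COIB")
    except (UnalignableSequenceError, ValueError) as exc:
        return CoibAssignment("failed", "failed", flags=[f"anchor-failed: {exc}"])
    seg = panel.segments["COIB"]
    vector: dict[str, str] = {}
    for site in panel.sites_for("COIB"):
        base = anch.site_base(seg, site.position)
        if base is None:
            return CoibAssignment(
                "failed", "failed", flags=[f"site-in-gap: {site.label}"]
            )
        if not is_unambiguous(base):
            return CoibAssignment(
                "failed", "failed", flags=[f"site-ambiguous: {site.label}"]
            )
        vector[site.label] = base

    best: tuple[int, str, tuple[str, ...]] | None = None
    for hap in panel.haplotypes_for("COIB"):
        mism = tuple(
            s for s, b in hap.allele_vector.items() if vector.get(s) != b
        )
        if not mism:
            return CoibAssignment(hap.label, "match", 0, hap.label)
        if best is None or len(mism) < best[0]:
            best = (len(mism), hap.label, mism)
    assert best is not None
    dist, nearest, mism = best
    strain, _ = call_coi_strain(anch, panel)
    prefix = {"CS": "CSa", "RS": "RSa"}.get(strain, "Xa")
    label = _next_auto_label(panel, prefix, run_suffix)
    if extend_panel:
        panel.haplotypes[label] = ReferenceHaplotype(
            label=label,
            segment="COIB",
            allele_vector=dict(vector),
            strain={"CS": "corn", "RS": "rice"}.get(strain, "not-applicable"),
        )
    return CoibAssignment(label, "novel", dist, nearest, mism)


def species_qc(
    seq, panel: MarkerPanel, max_distance: int = 1
) -> tuple[bool, int | None]:
    """Species check on the COIB segment.

    Passes iff the minimum Hamming distance (over aligned, ungapped
    columns) to any panel COIB reference haplotype is <= ``max_distance``
    (default: one substitution).  Returns (passed, min_distance);
    unalignable sequences fail with distance None.
    """
    try:
        anch = _anchor(seq, panel, "COIB")
    except (UnalignableSequenceError, ValueError):
        return False, None
    seg = panel.segments["COIB"]
    best: int | None = None
    for hap in panel.haplotypes_for("COIB"):
        hap_seq = panel.haplotype_sequence(hap.label)
        dist = 0
        for ref_pos in range(1, len(seg.reference_sequence) + 1):
            qbase = anch.query_base(ref_pos)
            if qbase is None:
                continue  # ungapped columns only
            if not compatible(qbase, hap_seq[ref_pos - 1]):
                dist += 1
        if best is None or dist < best:
            best = dist
    return best is not None and best <= max_distance, best


# ---------------------------------------------------------------------------
# TpiE4


def call_tpi_strain(seq, panel: MarkerPanel) -> tuple[str, list[str]]:
    """Tpi strain from gTpi183Y: C -> TpiC, T -> TpiR, Y -> TpiH."""
    try:
        anch = _anchor(seq, panel, "TpiE4")
    except (UnalignableSequenceError, ValueError) as exc:
        return "unknown", [f"tpi-anchor-failed: {exc}"]
    seg = panel.segments["TpiE4"]
    base = anch.site_base(seg, panel.sites["gTpi183Y"].position)
    if base is None:
        return "unknown", ["tpi-site-unmapped"]
    return {"C": "TpiC", "T": "TpiR", "Y": "TpiH"}.get(base, "unknown"), (
        [] if base in "CTY" else [f"tpi-unexpected-code-{base}183"]
    )


@dataclass
class TpiGenotype:
    """Result of TpiE4 genotype resolution."""

    genotype: str  # Ca1 / Ca2 / Ra1 / C-YY / H-CC / H-YY / ambiguous / failed
    haplotypes: tuple[str, ...] = ()  # constituent panel haplotype labels
    strains: tuple[str, ...] = ()  # strains of the constituents
    candidates: tuple[tuple[str, ...], ...] = ()  # when ambiguous
    flags: list[str] = field(default_factory=list)

    @property
    def strain(self) -> str:
        """TpiC / TpiR / TpiH / unknown, derived from the constituents."""
        if self.genotype in ("ambiguous", "failed") or not self.haplotypes:
            return "unknown"
        strains = set(self.strains)
        if strains == {"corn"}:
            return "TpiC"
        if strains == {"rice"}:
            return "TpiR"
        return "TpiH"


def assign_tpie4_genotype(seq, panel: MarkerPanel) -> TpiGenotype:
    """Resolve a TpiE4 consensus sequence to a haplotype or heterozygote pair.

    An unambiguous allele vector matching a panel haplotype is a
    hemizygous/homozygous call.  A vector containing IUPAC ambiguity codes
    is decoded by searching for the unique unordered pair of panel
    haplotypes whose site-wise IUPAC union equals the observed vector
    (TpiC-YY = Ca1/Ca2, TpiH-CC = Ca1/Ra1, TpiH-YY = Ca2/Ra1 on the
    African panel).  No consistent single or pair -> ambiguous; several
    consistent pairs (possible only with extended panels) -> ambiguous
    with all candidates listed.
    """
    try:
        anch = _anchor(seq, panel, "TpiE4")
    except (UnalignableSequenceError, ValueError) as exc:
        return _with_strains(
            TpiGenotype("failed", flags=[f"anchor-failed: {exc}"]), panel
        )
    seg = panel.segments["TpiE4"]
    sites = sorted(panel.sites_for("TpiE4"), key=lambda s: s.position)
    vector: dict[str, str] = {}
    for site in sites:
        base = anch.site_base(seg, site.position)
        if base is None:
            return _with_strains(
                TpiGenotype("failed", flags=[f"site-in-gap: {site.label}"]), panel
            )
        vector[site.label] = base

    haps = panel.haplotypes_for("TpiE4")
    if all(is_unambiguous(b) for b in vector.values()):
        for hap in haps:
            if all(vector[s] == b for s, b in hap.allele_vector.items()):
                return _with_strains(
                    TpiGenotype(_short(hap.label), (hap.label,)), panel
                )
        return _with_strains(
            TpiGenotype("ambiguous", flags=["no-matching-haplotype"]), panel
        )

    consistent: list[tuple[str, str]] = []
    for ha, hb in itertools.combinations(haps, 2):
        expected = {
            s.label: union_code(ha.allele_vector[s.label], hb.allele_vector[s.label])
            for s in sites
        }
        if expected == vector:
            consistent.append((ha.label, hb.label))
    if len(consistent) == 1:
        pair = consistent[0]
        return _with_strains(TpiGenotype(panel.pair_label(*pair), pair), panel)
    if not consistent:
        return _with_strains(
            TpiGenotype("ambiguous", flags=["no-consistent-pair"]), panel
        )
    return _with_strains(
        TpiGenotype(
            "ambiguous",
            candidates=tuple(consistent),
            flags=["multiple-consistent-pairs"],
        ),
        panel,
    )


def _with_strains(gt: TpiGenotype, panel: MarkerPanel) -> TpiGenotype:
    gt.strains = tuple(panel.haplotypes[h].strain for h in gt.haplotypes)
    return gt


# ---------------------------------------------------------------------------
# TpiI4


@dataclass
class Tpii4Call:
    """Result of TpiI4 intron haplotype assignment."""

    call: str  # panel label, "heterozygous", "novel", or "failed"
    flags: list[str] = field(default_factory=list)


def assign_tpii4_haplotype(seq, panel: MarkerPanel) -> Tpii4Call:
    """Assign a TpiI4 intron core sequence to a panel haplotype.

    The base at any poor-signal site (gTpiI4[131]R in the default panel)
    is forced to its consensus before matching.  A sequence with any
    remaining IUPAC ambiguity inside the core, or indel evidence
    incompatible with a single panel haplotype, is heterozygous (the
    consensus of two different Z-chromosome alleles).  Otherwise an exact
    match of core alleles plus indel features returns the haplotype
    label; no match returns novel.
    """
    seg = panel.segments["TpiI4"]
    try:
        anch = _anchor(seq, panel, "TpiI4")
    except (UnalignableSequenceError, ValueError) as exc:
        return Tpii4Call("failed", [f"anchor-failed: {exc}"])
    core = range(seg.core_start, seg.core_end + 1)
    forced = {
        s.position: s.force_base
        for s in panel.sites_for("TpiI4")
        if s.force_base is not None
    }
    observed: dict[int, str | None] = {}
    missing = deletions = 0
    for pos in core:
        ref_pos = seg.to_ref_pos(pos)
        if ref_pos not in anch.ref_to_query:
            missing += 1
            continue
        base = anch.query_base(ref_pos)
        if base is None:
            deletions += 1
            observed[pos] = None
            continue
        observed[pos] = forced.get(pos, base)
    if missing:
        return Tpii4Call("failed", [f"core-not-covered ({missing} nt missing)"])

    ambiguous = [p for p, b in observed.items() if b is not None and not is_unambiguous(b)]
    if ambiguous:
        return Tpii4Call("heterozygous", [f"in-core-ambiguity at {ambiguous}"])

    core_insertions = [
        (pos, length)
        for pos, length in anch.insertions
        if seg.core_start <= pos + seg.origin_offset <= seg.core_end
    ]
    if deletions:
        # no panel haplotype carries a core deletion: mixed-allele signal
        return Tpii4Call("heterozygous", ["in-core-deletion"])

    for hap in panel.haplotypes_for("TpiI4"):
        hap_seq = panel.haplotype_sequence(hap.label, with_indels=False)
        expected = {
            pos: forced.get(pos, hap_seq[seg.to_ref_pos(pos) - 1]) for pos in core
        }
        if expected != observed:
            continue
        feats = [f for f in hap.indel_features if f.kind == "insertion"]
        if len(feats) != len(core_insertions):
            continue
        if all(
            any(
                abs(f.position - (pos + seg.origin_offset)) <= INDEL_POS_TOL
                and abs(f.length - length) <= INDEL_LEN_TOL
                for pos, length in core_insertions
            )
            for f in feats
        ):
            return Tpii4Call(hap.label)
    if core_insertions:
        return Tpii4Call(
            "heterozygous",
            [f"indel-evidence-unmatched: insertions {core_insertions}"],
        )
    return Tpii4Call("novel")


# ---------------------------------------------------------------------------
# Whole-specimen classification


@dataclass
class SpecimenCall:
    """Per-specimen classification result across all three segments."""

    specimen_id: str
    collection_label: str = ""
    source_type: str = "larva"  # "male_trap" | "larva"
    coib_haplotype: str = "failed"
    coi_strain: str = "unknown"  # "CS" | "RS" | "unknown"
    h_config: str = "not-applicable"
    tpie4_genotype: str = "failed"
    tpi_strain: str = "unknown"  # "TpiC" | "TpiR" | "TpiH" | "unknown"
    tpii4_call: str = "failed"
    qc_flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict[str, str]:
        return {
            "specimen_id": self.specimen_id,
            "collection": self.collection_label,
            "source_type": self.source_type,
            "coib_haplotype": self.coib_haplotype,
            "coi_strain": self.coi_strain,
            "h_config": self.h_config,
            "tpie4_genotype": self.tpie4_genotype,
            "tpi_strain": self.tpi_strain,
            "tpii4_call": self.tpii4_call,
            "qc_flags": ";".join(self.qc_flags),
        }


def classify_specimen(
    specimen_id: str,
    sequences: dict[str, str | None],
    panel: MarkerPanel,
    collection_label: str = "",
    source_type: str = "larva",
) -> SpecimenCall:
    """Classify one specimen from its per-segment consensus sequences.

    ``sequences`` maps segment name (COIB / TpiE4 / TpiI4) to the Sanger
    consensus sequence, or None / absent for a failed reaction.  The Tpi
    strain is derived from the resolved TpiE4 genotype so that the two
    stay consistent; unresolved genotypes leave it unknown.
    """
    call = SpecimenCall(specimen_id, collection_label, source_type)
    coib = sequences.get("COIB")
    if coib:
        try:
            anch = _anchor(coib, panel, "COIB")
        except (UnalignableSequenceError, ValueError) as exc:
            anch = None
            call.qc_flags.append(f"coib-anchor-failed: {exc}")
        if anch is not None:
            passed, dist = species_qc(anch, panel)
            if not passed:
                call.qc_flags.append(
                    f"species-check-failed (min distance {dist})"
                )
            call.coi_strain, flags = call_coi_strain(anch, panel)
            call.qc_flags.extend(flags)
            call.h_config = coib_h_config(anch, panel)
            assignment = assign_coib_haplotype(anch, panel)
            call.coib_haplotype = (
                assignment.label if assignment.status != "failed" else "failed"
            )
            if assignment.status == "novel":
                call.qc_flags.append(
                    f"novel-coib ({assignment.distance} sites from "
                    f"{assignment.nearest})"
                )
            call.qc_flags.extend(assignment.flags)
    tpie4 = sequences.get("TpiE4")
    if tpie4:
        gt = assign_tpie4_genotype(tpie4, panel)
        call.tpie4_genotype = gt.genotype
        call.tpi_strain = gt.strain
        call.qc_flags.extend(gt.flags)
    tpii4 = sequences.get("TpiI4")
    if tpii4:
        res = assign_tpii4_haplotype(tpii4, panel)
        call.tpii4_call = res.call
        call.qc_flags.extend(res.flags)
    if call.coi_strain == "RS":
        call.h_config = "not-applicable"
    return call
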