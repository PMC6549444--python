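"""Marker panel: gene segments, diagnostic sites and reference haplotypes.

The panel is configuration-driven.  A panel file (YAML) defines, for each
amplified gene segment, a reference nucleotide sequence together with the
coordinate convention used in site names, the diagnostic single-nucleotide
sites with their allele meanings, and the reference haplotypes as allele
vectors over those sites (optionally with indel features such as the large
intron insertion that distinguishes TpiI4Ca1b).  The classification engine
is panel-agnostic: extending the panel with new haplotypes requires no code
change.

Site nomenclature follows the field convention: an ``m`` prefix marks a
mitochondrial site, ``g`` a nuclear (genomic) one, followed by the gene
segment name, the 1-based offset from the segment's coordinate origin
(translational start for COI, 5' exon start for TpiE4, 5' intron start for
TpiI4) and the IUPAC code of the alleles observed, e.g. ``mCOI1164D``.

The packaged default panel describes the three segments used to genotype
African fall armyworm (*Spodoptera frugiperda*): the 603-bp COIB
mitochondrial amplicon, the ~199-bp TpiE4 exon segment and the 162-bp TpiI4
intron core.  Its backbone sequences are synthetic stand-ins (the deposited
amplicon sequences are not redistributed here); every diagnostic-site
allele, haplotype configuration and indel feature matches the published
marker definitions, which is all the classification logic reads.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .iupac import UNAMBIGUOUS, bases

STRAINS = ("corn", "rice", "not-applicable")


@dataclass(frozen=True)
class MarkerSegment:
    """One amplified gene segment and its coordinate convention.

    ``origin_offset`` converts a site coordinate (counted from the
    biological origin named in ``coordinate_origin``) into a 1-based
    position on ``reference_sequence``: ref_pos = site_pos - origin_offset.
    """

    name: str
    reference_sequence: str
    coordinate_origin: str
    origin_offset: int = 0
    expected_length: int | None = None
    core_start: int | None = None  # segment coordinates, inclusive
    core_end: int | None = None

    def __post_init__(self) -> None:
        if not set(self.reference_sequence) <= set("ACGT"):
            bad = sorted(set(self.reference_sequence) - set("ACGT"))
            raise ValueError(
                f"segment {self.name}: reference contains non-ACGT {bad}"
            )

    def to_ref_pos(self, site_position: int) -> int:
        """1-based reference position for a site coordinate."""
        return site_position - self.origin_offset

    def contains(self, site_position: int) -> bool:
        return 1 <= self.to_ref_pos(site_position) <= len(self.reference_sequence)

    def reference_base(self, site_position: int) -> str:
        return self.reference_sequence[self.to_ref_pos(site_position) - 1]


@dataclass(frozen=True)
class DiagnosticSite:
    """A named polymorphic position with its allele -> meaning map."""

    label: str
    segment: str
    position: int  # 1-based, from the segment's coordinate origin
    allele_meaning: dict[str, str]
    force_base: str | None = None  # consensus assumed at poor-signal sites

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site {self.label}: position must be >= 1")
        alleles = set(self.allele_meaning)
        if not alleles <= UNAMBIGUOUS:
            raise ValueError(f"site {self.label}: alleles must be in ACGT")
        # the IUPAC suffix of the label advertises the observed alleles;
        # the meaning map must cover at least those
        suffix = self.label.rstrip("]")[-1]
        if suffix in "ACGTRYSWKMBDHVN" and suffix.isalpha():
            if not bases(suffix) <= alleles and suffix in "RYSWKMBDHVN":
                raise ValueError(
                    f"site {self.label}: meaning map {sorted(alleles)} does not "
                    f"cover the alleles admitted by the label suffix {suffix}"
                )

    def meaning(self, base: str) -> str:
        return self.allele_meaning.get(base, "unobserved-in-species")


@dataclass(frozen=True)
class IndelFeature:
    """An insertion/deletion feature of a haplotype, in segment coordinates.

    ``position`` is the segment coordinate after which an insertion occurs
    (or at which a deletion starts).  ``sequence`` is required for
    insertions so the simulator can emit the full-length variant.
    """

    kind: str  # "insertion" | "deletion"
    position: int
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if self.kind == "insertion" and self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError("insertion sequence length mismatch")


@dataclass(frozen=True)
class ReferenceHaplotype:
    """A labeled allele vector over a segment's diagnostic sites."""

    label: str
    segment: str
    allele_vector: dict[str, str]  # site label -> unambiguous base
    strain: str = "not-applicable"
    indel_features: tuple[IndelFeature, ...] = ()
    extra_substitutions: dict[int, str] = field(default_factory=dict)
    exon_link: str | None = None  # TpiI4 haplotype -> TpiE4 haplotype

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"haplotype {self.label}: bad strain {self.strain!r}")
        for site, base in self.allele_vector.items():
            if base not in UNAMBIGUOUS:
                raise ValueError(
                    f"haplotype {self.label}: ambiguous allele {base} at {site}"
                )


class MarkerPanel:
    """Validated collection of segments, sites and reference haplotypes."""

    def __init__(
        self,
        segments: dict[str, MarkerSegment],
        sites: list[DiagnosticSite],
        haplotypes: list[ReferenceHaplotype],
        name: str = "panel",
        pair_labels: dict[frozenset[str], str] | None = None,
    ) -> None:
        self.name = name
        self.segments = segments
        self.sites = {s.label: s for s in sites}
        self.haplotypes = {h.label: h for h in haplotypes}
        self.pair_labels = pair_labels or {}
        self._validate()

    # -- lookups ---------------------------------------------------------
    def sites_for(self, segment: str) -> list[DiagnosticSite]:
        return [s for s in self.sites.values() if s.segment == segment]

    def haplotypes_for(self, segment: str) -> list[ReferenceHaplotype]:
        return [h for h in self.haplotypes.values() if h.segment == segment]

    def haplotype_sequence(self, label: str, with_indels: bool = True) -> str:
        """Full segment-length sequence of a reference haplotype.

        The segment reference is edited at every diagnostic site (and any
        extra substitutions) to the haplotype's alleles; insertion features
        are spliced in when ``with_indels``.
        """
        hap = self.haplotypes[label]
        seg = self.segments[hap.segment]
        seq = list(seg.reference_sequence)
        for site_label, base in hap.allele_vector.items():
            seq[seg.to_ref_pos(self.sites[site_label].position) - 1] = base
        for pos, base in hap.extra_substitutions.items():
            seq[seg.to_ref_pos(pos) - 1] = base
        if with_indels:
            for feat in sorted(hap.indel_features, key=lambda f: -f.position):
                ref_pos = seg.to_ref_pos(feat.position)
                if feat.kind == "insertion":
                    seq[ref_pos:ref_pos] = list(feat.sequence or "N" * feat.length)
                else:
                    del seq[ref_pos - 1 : ref_pos - 1 + feat.length]
        return "".join(seq)

    def pair_label(self, a: str, b: str) -> str:
        """Reporting label for an unordered heterozygote pair."""
        key = frozenset((a, b))
        if key in self.pair_labels:
            return self.pair_labels[key]
        return "/".join(sorted((a, b)))

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        for site in self.sites.values():
            seg = self.segments.get(site.segment)
            if seg is None:
                raise ValueError(f"site {site.label}: unknown segment {site.segment}")
            if not seg.contains(site.position):
                raise ValueError(
                    f"site {site.label}: position {site.position} falls outside "
                    f"the {site.segment} reference"
                )
        by_segment: dict[str, dict[tuple, str]] = {}
        for hap in self.haplotypes.values():
            if hap.segment not in self.segments:
                raise ValueError(f"haplotype {hap.label}: unknown segment")
            seg_sites = {s.label for s in self.sites_for(hap.segment)}
            if not set(hap.allele_vector) <= seg_sites:
                extra = set(hap.allele_vector) - seg_sites
                raise ValueError(f"haplotype {hap.label}: unknown sites {extra}")
            key = (
                tuple(sorted(hap.allele_vector.items())),
                tuple(sorted(hap.extra_substitutions.items())),
                tuple((f.kind, f.position, f.length) for f in hap.indel_features),
            )
            seen = by_segment.setdefault(hap.segment, {})
            if key in seen:
                raise ValueError(
                    f"haplotypes {seen[key]} and {hap.label} are indistinguishable"
                )
            seen[key] = hap.label


# ---------------------------------------------------------------------------
# YAML serialization


def panel_from_dict(doc: dict) -> MarkerPanel:
    segments = {
        name: MarkerSegment(
            name=name,
            reference_sequence=d["reference"].upper(),
            coordinate_origin=d.get("coordinate_origin", ""),
            origin_offset=int(d.get("origin_offset", 0)),
            expected_length=d.get("expected_length"),
            core_start=d.get("core_start"),
            core_end=d.get("core_end"),
        )
        for name, d in doc["segments"].items()
    }
    sites = [
        DiagnosticSite(
            label=d["label"],
            segment=d["segment"],
            position=int(d["position"]),
            allele_meaning={k.upper(): v for k, v in d["alleles"].items()},
            force_base=d.get("force_base"),
        )
        for d in doc["sites"]
    ]
    haplotypes = []
    for d in doc["haplotypes"]:
        feats = tuple(
            IndelFeature(
                kind=f["kind"],
                position=int(f["position"]),
                length=int(f["length"]),
                sequence=f.get("sequence"),
            )
            for f in d.get("indels", [])
        )
        haplotypes.append(
            ReferenceHaplotype(
                label=d["label"],
                segment=d["segment"],
                allele_vector={k: v.upper() for k, v in d.get("alleles", {}).items()},
                strain=d.get("strain", "not-applicable"),
                indel_features=feats,
                extra_substitutions={
                    int(k): v.upper() for k, v in d.get("substitutions", {}).items()
                },
                exon_link=d.get("exon_link"),
            )
        )
    pair_labels = {
        frozenset(k.split("+")): v for k, v in doc.get("pair_labels", {}).items()
    }
    return MarkerPanel(
        segments,
        sites,
        haplotypes,
        name=doc.get("panel_name", "panel"),
        pair_labels=pair_labels,
    )


def load_panel(path) -> MarkerPanel:
    """Load a panel from a YAML file."""
    with open(path) as fh:
        return panel_from_dict(yaml.safe_load(fh))


def default_panel() -> MarkerPanel:
    """The packaged African fall armyworm COIB / TpiE4 / TpiI4 panel."""
    ref = importlib.resources.files("fawhap.data").joinpath("default_panel.yaml")
    return panel_from_dict(yaml.safe_load(ref.read_text()))
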