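"""Pairwise anchoring of amplicon reads to a segment reference.

Queries are never interpreted by absolute offset: amplicons may start at
primer positions inside the segment and the Tpi intron carries indels, so
every diagnostic site is located through a gap-aware pairwise alignment of
the query to the segment reference.  Scoring: match +1, mismatch -1,
affine gaps (open -5, extend -0.5); an IUPAC ambiguity code scores as a
match against any base it admits (a heterozygote's Y really is a C or a T
on each chromosome).  End gaps are free so partial amplicons anchor
cleanly.

A fast path handles the common case of an indel-free query with the same
length as the reference (column-wise comparison, no dynamic programming);
anything else falls through to :class:`Bio.Align.PairwiseAligner`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .iupac import IUPAC_SETS, compatible
from .panel import MarkerSegment

DEFAULT_IDENTITY_FLOOR = 0.80
MIN_QUERY_LENGTH = 50

_ALPHABET = "ACGTRYSWKMBDHVN"


class UnalignableSequenceError(ValueError):
    """Raised when a query cannot be anchored above the identity floor."""


def _iupac_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = 1.0 if IUPAC_SETS[a] & IUPAC_SETS[b] else -1.0
    return m


_MATRIX = _iupac_matrix()


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _MATRIX
    al.open_gap_score = -5.0
    al.extend_gap_score = -0.5
    # end-gap asymmetry: a query covering only part of the segment is free
    # (reads may start at internal primer positions), while query overhang
    # beyond the reference pays a light per-base cost -- otherwise a long
    # internal insertion (e.g. the 200-bp TpiI4Ca1b block) scores better
    # absorbed into free end gaps than reported as a gap.
    al.end_deletion_score = 0.0  # reference columns uncovered at the ends
    al.end_insertion_score = -0.5  # query overhang past the reference
    return al


@dataclass
class Anchoring:
    """Gap-aware mapping of reference coordinates onto a query sequence.

    ``ref_to_query`` maps every 1-based reference position covered by the
    alignment to a 0-based query index, or ``None`` when that reference
    column sits in a query gap (deletion).  ``insertions`` records query
    material absent from the reference as ``(ref_pos_after, length)``.
    """

    segment: str
    query: str
    identity: float
    ref_to_query: dict[int, int | None]
    insertions: list[tuple[int, int]] = field(default_factory=list)

    def query_base(self, ref_pos: int) -> str | None:
        """Query base aligned to a reference position; None if unmapped/gap."""
        qi = self.ref_to_query.get(ref_pos)
        return None if qi is None else self.query[qi]

    def site_base(self, segment: MarkerSegment, site_position: int) -> str | None:
        """Query base at a diagnostic-site coordinate (segment numbering)."""
        return self.query_base(segment.to_ref_pos(site_position))


def _fast_identity(query: str, reference: str) -> float:
    q = np.frombuffer(query.encode(), dtype="S1")
    r = np.frombuffer(reference.encode(), dtype="S1")
    exact = q == r
    if exact.all():
        return 1.0
    ok = exact.copy()
    for i in np.nonzero(~exact)[0]:
        ok[i] = compatible(query[i], reference[i])
    return float(ok.mean())


def anchor_to_reference(
    query: str,
    segment: MarkerSegment,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> Anchoring:
    """Anchor an amplicon read to a segment reference.

    Raises
    ------
    ValueError
        If the query is shorter than 50 nt.
    UnalignableSequenceError
        If alignment identity over aligned columns falls below
        ``identity_floor``.
    """
    query = query.upper()
    if len(query) <= MIN_QUERY_LENGTH:
        raise ValueError(
            f"query too short to anchor ({len(query)} <= {MIN_QUERY_LENGTH} nt)"
        )
    reference = segment.reference_sequence

    # fast path: equal length, no indels needed
    if len(query) == len(reference):
        identity = _fast_identity(query, reference)
        if identity >= identity_floor:
            return Anchoring(
                segment=segment.name,
                query=query,
                identity=identity,
                ref_to_query={i + 1: i for i in range(len(reference))},
            )

    alignment = _aligner().align(reference, query)[0]
    ref_to_query: dict[int, int | None] = {}
    insertions: list[tuple[int, int]] = []
    matches = columns = 0
    r_blocks, q_blocks = (
        [(int(x0), int(x1)) for x0, x1 in blocks] for blocks in alignment.aligned
    )
    prev_r_end = prev_q_end = None
    for (r0, r1), (q0, q1) in zip(r_blocks, q_blocks):
        if prev_r_end is not None:
            if r0 > prev_r_end:  # deletion in query
                for rp in range(prev_r_end, r0):
                    ref_to_query[rp + 1] = None
            if q0 > prev_q_end:  # insertion relative to reference
                insertions.append((prev_r_end, q0 - prev_q_end))
        for k in range(r1 - r0):
            ref_to_query[r0 + k + 1] = q0 + k
            columns += 1
            if compatible(reference[r0 + k], query[q0 + k]):
                matches += 1
        prev_r_end, prev_q_end = r1, q1
    identity = matches / columns if columns else 0.0
    if identity < identity_floor:
        raise UnalignableSequenceError(
            f"{segment.name}: alignment identity {identity:.2f} below floor "
            f"{identity_floor:.2f}"
        )
    return Anchoring(
        segment=segment.name,
        query=query,
        identity=identity,
        ref_to_query=ref_to_query,
        insertions=insertions,
    )
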