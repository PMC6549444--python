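"""Tamura-Nei distances, neighbor-joining and clade-composition reports.

Stand-in for the intron-haplotype tree analysis: pairwise TN93 distances
among TpiI4 sequences, a Saitou-Nei neighbor-joining tree, and, for a
focal tip, the host-plant / COI-strain composition of each nested clade
containing it.  TN93 models distinct rates for the two transition classes
(A<->G within purines, C<->T within pyrimidines) and a common
transversion rate, with empirical base frequencies estimated from the
pooled sequence pair.  Sites with a gap or ambiguity code in either
sequence are excluded pair by pair (pairwise deletion), so length-variable
intron regions do not erase the comparable core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

MIN_COMPARABLE_SITES = 20

HOST_CLASSES = ("CS-host", "RS-host", "unknown")
COI_CLASSES = ("CS", "RS", "unknown")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class UndefinedDistanceError(ValueError):
    """Too few comparable sites to estimate a distance."""


@dataclass(frozen=True)
class TipAnnotation:
    """Host-plant class and COI strain attached to one tree tip.

    CS hosts are maize/sorghum (corn-strain preferred); RS hosts are
    turf/pasture grasses (rice-strain preferred).
    """

    tip_id: str
    haplotype: str = ""
    host_class: str = "unknown"
    coi_strain: str = "unknown"
    region: str = ""

    def __post_init__(self) -> None:
        if not self.tip_id:
            raise ValueError("tip_id must be nonempty")
        if self.host_class not in HOST_CLASSES:
            raise ValueError(f"unknown host_class {self.host_class!r}")
        if self.coi_strain not in COI_CLASSES:
            raise ValueError(f"unknown coi_strain {self.coi_strain!r}")


def tn93_distance(a: str, b: str) -> float:
    """Tamura-Nei (TN93) distance in substitutions/site.

    Sequences must be positionally aligned (equal length).  Base
    frequencies are estimated from the pooled pair.  Returns ``math.inf``
    when substitution saturation drives a logarithm argument to or below
    zero.  Raises :class:`UndefinedDistanceError` with fewer than 20
    comparable (unambiguous, ungapped in both) sites.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    a = a.upper()
    b = b.upper()
    counts = {base: 0 for base in "ACGT"}
    n = 0
    p1 = p2 = q = 0  # A<->G, C<->T, transversions
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue  # pairwise deletion of gaps/ambiguities
        n += 1
        counts[x] += 1
        counts[y] += 1
        if x == y:
            continue
        pair = {x, y}
        if pair <= _PURINES:
            p1 += 1
        elif pair <= _PYRIMIDINES:
            p2 += 1
        else:
            q += 1
    if n < MIN_COMPARABLE_SITES:
        raise UndefinedDistanceError(
            f"only {n} comparable sites (< {MIN_COMPARABLE_SITES})"
        )
    if p1 == p2 == q == 0:
        return 0.0
    freqs = {base: c / (2 * n) for base, c in counts.items()}
    ga, gc, gg, gt = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    gr = ga + gg
    gy = gc + gt
    P1, P2, Q = p1 / n, p2 / n, q / n
    if min(gr, gy) == 0:
        return math.inf
    k1 = 2 * ga * gg / gr
    k2 = 2 * gc * gt / gy
    k3 = 2 * (gr * gy - ga * gg * gy / gr - gc * gt * gr / gy)
    w1 = (1 - P1 / k1 - Q / (2 * gr)) if k1 > 0 else 1.0
    w2 = (1 - P2 / k2 - Q / (2 * gy)) if k2 > 0 else 1.0
    w3 = 1 - Q / (2 * gr * gy)
    if min(w1, w2, w3) <= 0:
        return math.inf
    d = -(k1 * math.log(w1)) - (k2 * math.log(w2)) - (k3 * math.log(w3))
    return max(d, 0.0)


def _pad(seqs: Mapping[str, str]) -> dict[str, str]:
    """Right-pad to equal length with gaps (pairwise deletion ignores them)."""
    width = max(len(s) for s in seqs.values())
    return {k: s + "-" * (width - len(s)) for k, s in seqs.items()}


def distance_matrix(
    sequences: Mapping[str, str], collapse_duplicates: bool = False
) -> DistanceMatrix:
    """Pairwise TN93 distance matrix for a set of aligned sequences.

    Ids are sorted so downstream neighbor-joining tie-breaking is
    deterministic.  With ``collapse_duplicates`` identical sequences are
    reduced to the lexicographically first id before computing distances.
    """
    seqs = dict(sequences)
    if collapse_duplicates:
        seen: dict[str, str] = {}
        for tip in sorted(seqs):
            seen.setdefault(seqs[tip], tip)
        seqs = {tip: s for s, tip in seen.items()}
    seqs = _pad(seqs)
    ids = sorted(seqs)
    m = np.zeros((len(ids), len(ids)))
    for i, u in enumerate(ids):
        for j in range(i + 1, len(ids)):
            m[i, j] = m[j, i] = tn93_distance(seqs[u], seqs[ids[j]])
    return DistanceMatrix(m, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining tree from a distance matrix.

    Negative branch-length estimates are clamped to zero with the deficit
    shifted to the adjacent branch, keeping path lengths additive.
    Requires >= 3 tips and finite entries.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining requires >= 3 tips")
    if not np.isfinite(dm.data).all():
        raise ValueError("distance matrix contains non-finite entries")
    return nj(dm, neg_as_zero=True)


@dataclass
class CladeReport:
    """Composition of one nested clade containing the focal tip."""

    size: int  # member tips excluding the focal tip
    members: tuple[str, ...]
    host_fractions: dict[str, float]
    coi_fractions: dict[str, float]


def clade_composition(
    tree: TreeNode,
    annotations: Iterable[TipAnnotation],
    focal_tip: str,
) -> list[CladeReport]:
    """Composition of every nested clade containing a focal tip.

    Walks outward from the focal tip through its ancestors; for each
    containing clade reports the fraction of member tips (the focal tip
    itself excluded) per host class and per COI strain.  The first entry
    is the smallest non-trivial containing clade — the headline metric.
    Unannotated tips count as class "unknown".
    """
    ann = {a.tip_id: a for a in annotations}
    try:
        node = tree.find(focal_tip)
    except Exception as exc:  # skbio raises MissingNodeError
        raise KeyError(f"focal tip {focal_tip!r} not in tree") from exc
    reports: list[CladeReport] = []
    for anc in node.ancestors():
        members = tuple(
            t.name for t in anc.tips() if t.name and t.name != focal_tip
        )
        if not members:
            continue
        if reports and len(members) == reports[-1].size:
            continue  # unary chain: same clade
        host = {c: 0 for c in HOST_CLASSES}
        coi = {c: 0 for c in COI_CLASSES}
        for m in members:
            a = ann.get(m)
            host[a.host_class if a else "unknown"] += 1
            coi[a.coi_strain if a else "unknown"] += 1
        n = len(members)
        reports.append(
            CladeReport(
                size=n,
                members=members,
                host_fractions={c: v / n for c, v in host.items()},
                coi_fractions={c: v / n for c, v in coi.items()},
            )
        )
    return reports
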