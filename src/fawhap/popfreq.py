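"""Collection-level counting, sex-linkage adjustment and frequency analysis.

*Tpi* sits on the Z chromosome: male Lepidoptera are ZZ (two copies,
heterozygotes possible), females ZW (hemizygous).  Specimen counts are
therefore converted to chromosome counts before computing allele
frequencies.  Each heterozygote contributes one chromosome to each of its
two constituent alleles; each unambiguous specimen contributes

* 2 chromosomes in all-male pheromone-trap collections, or
* 1.5 chromosomes in larval collections of unknown sex, assuming a 1:1
  sex ratio ((2 in males + 1 in females) / 2).

Reported adjusted counts are rounded half-up to integers.  Mean
frequencies across collections are UNWEIGHTED (each collection is one
unit); the specimen-weighted pooled share is exposed separately.  The
regional comparison is a two-sided Welch t-test on per-collection
proportions (a pooled-variance Student's t is available as an option).
No multiple-testing correction is applied.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .classify import SpecimenCall

TPIE4_CLASSES = ("Ca1", "Ca2", "Ra1", "C-YY", "H-CC", "H-YY")
TPI_ALLELES = ("Ca1", "Ca2", "Ra1")
HET_CONSTITUENTS = {
    "C-YY": ("Ca1", "Ca2"),
    "H-CC": ("Ca1", "Ra1"),
    "H-YY": ("Ca2", "Ra1"),
}
CONFIG_CELLS = (
    "CS·TpiC", "CS·TpiR", "CS·TpiH", "RS·TpiC", "RS·TpiR", "RS·TpiH",
)


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


def strain_configuration(coi_strain: str, tpi_strain: str) -> tuple[str, str]:
    """Classify the mito-nuclear marker configuration of one specimen.

    Returns (category, cell) with category one of Concordant (CS·TpiC,
    RS·TpiR), Discordant (CS·TpiR, RS·TpiC) or Heterozygous (CS·TpiH,
    RS·TpiH).  Raises ValueError when either strain is unknown (such
    records are excluded upstream).
    """
    if coi_strain not in ("CS", "RS") or tpi_strain not in ("TpiC", "TpiR", "TpiH"):
        raise ValueError(
            f"configuration undefined for ({coi_strain}, {tpi_strain})"
        )
    cell = f"{coi_strain}·{tpi_strain}"
    if tpi_strain == "TpiH":
        return "Heterozygous", cell
    concordant = (coi_strain == "CS") == (tpi_strain == "TpiC")
    return ("Concordant" if concordant else "Discordant"), cell


@dataclass
class CollectionCounts:
    """Observed specimen counts for one collection."""

    collection_label: str
    source_type: str  # "male_trap" | "larva"
    n_specimens_total: int = 0
    coib_counts: dict[str, int] = field(default_factory=dict)
    tpie4_counts: dict[str, int] = field(default_factory=dict)
    tpii4_counts: dict[str, int] = field(default_factory=dict)
    tpii4_heterozygous: int = 0
    config_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.coib_counts, self.tpie4_counts, self.tpii4_counts):
            if any(v < 0 for v in mapping.values()):
                raise ValueError("counts must be nonnegative")


@dataclass
class AdjustedCounts:
    """Chromosome-basis Tpi allele counts for one collection."""

    collection_label: str
    multiplier: float
    raw: dict[str, float]
    reported: dict[str, int]
    total_chromosomes: float


def tabulate_collection(calls: Iterable[SpecimenCall]) -> CollectionCounts:
    """Aggregate specimen calls from a single collection into counts.

    Specimens with a failed or ambiguous call for one marker are excluded
    from that marker's counts only.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no calls to tabulate")
    labels = {c.collection_label for c in calls}
    if len(labels) > 1:
        raise ValueError(f"mixed collection labels: {sorted(labels)}")
    sources = {c.source_type for c in calls}
    if len(sources) > 1:
        raise ValueError(f"mixed source types: {sorted(sources)}")
    out = CollectionCounts(
        collection_label=labels.pop(),
        source_type=sources.pop(),
        n_specimens_total=len(calls),
    )
    for c in calls:
        if c.coib_haplotype not in ("failed",):
            short = c.coib_haplotype.removeprefix("COI-")
            out.coib_counts[short] = out.coib_counts.get(short, 0) + 1
        if c.tpie4_genotype not in ("failed", "ambiguous"):
            out.tpie4_counts[c.tpie4_genotype] = (
                out.tpie4_counts.get(c.tpie4_genotype, 0) + 1
            )
        if c.tpii4_call == "heterozygous":
            out.tpii4_heterozygous += 1
        elif c.tpii4_call not in ("failed", "novel"):
            short = c.tpii4_call.removeprefix("TpiI4")
            out.tpii4_counts[short] = out.tpii4_counts.get(short, 0) + 1
        try:
            _, cell = strain_configuration(c.coi_strain, c.tpi_strain)
        except ValueError:
            pass
        else:
            out.config_counts[cell] = out.config_counts.get(cell, 0) + 1
    return out


def adjust_tpi_counts(
    counts: CollectionCounts, larval_sex_ratio: float = 0.5
) -> AdjustedCounts:
    """Convert observed TpiE4 specimen counts to chromosome counts.

    Unambiguous specimens are weighted by 2 (male_trap: all male, ZZ) or
    by ``2*r + (1-r)`` for larvae with male fraction ``r`` (1.5 under the
    default 1:1 sex ratio); each heterozygote class adds one chromosome
    to each of its two constituent alleles.  Reported counts are rounded
    half-up.
    """
    if counts.source_type == "male_trap":
        m = 2.0
    elif counts.source_type == "larva":
        m = 2.0 * larval_sex_ratio + (1.0 - larval_sex_ratio)
    else:
        raise ValueError(f"unknown source_type {counts.source_type!r}")
    c = counts.tpie4_counts
    raw = {a: m * c.get(a, 0) for a in TPI_ALLELES}
    for het, (x, y) in HET_CONSTITUENTS.items():
        raw[x] += c.get(het, 0)
        raw[y] += c.get(het, 0)
    return AdjustedCounts(
        collection_label=counts.collection_label,
        multiplier=m,
        raw=raw,
        reported={a: round_half_up(v) for a, v in raw.items()},
        total_chromosomes=sum(raw.values()),
    )


# ---------------------------------------------------------------------------
# Frequencies


@dataclass
class FrequencySummary:
    """Per-collection proportions of one quantity with unweighted mean/sd."""

    quantity: str
    per_collection: dict[str, float]
    mean: float
    sd: float
    pooled: float | None = None  # specimen-weighted alternative


def frequency_summary(
    tables: Mapping[str, Mapping[str, float]],
    numerator: str | Iterable[str],
    denominator: Iterable[str] | None = None,
    quantity: str | None = None,
) -> FrequencySummary:
    """Per-collection proportion of ``numerator`` classes, with group mean.

    ``tables`` maps collection label -> {class: count}.  The denominator
    defaults to all classes of each collection's table.  The group mean is
    the unweighted arithmetic mean over collections; sd is the sample
    standard deviation (n-1).  Collections with a zero denominator are
    omitted with a warning.
    """
    num = (numerator,) if isinstance(numerator, str) else tuple(numerator)
    den = None if denominator is None else tuple(denominator)
    per: dict[str, float] = {}
    num_total = den_total = 0.0
    for label, table in tables.items():
        d = sum(table.values()) if den is None else sum(table.get(k, 0) for k in den)
        n = sum(table.get(k, 0) for k in num)
        if d == 0:
            warnings.warn(
                f"collection {label}: zero denominator, omitted", stacklevel=2
            )
            continue
        per[label] = n / d
        num_total += n
        den_total += d
    if not per:
        raise ValueError("no collection has a nonzero denominator")
    values = np.array(list(per.values()))
    return FrequencySummary(
        quantity=quantity or "+".join(num),
        per_collection=per,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        pooled=num_total / den_total if den_total else None,
    )


def pooled_shares(
    tables: Mapping[str, Mapping[str, float]],
    numerator: str | Iterable[str],
    denominator: Iterable[str],
) -> tuple[float, int]:
    """Specimen-weighted pooled share across collections.

    Returns (proportion, percent rounded half-up to integer).
    """
    num = (numerator,) if isinstance(numerator, str) else tuple(numerator)
    den = tuple(denominator)
    n = sum(sum(t.get(k, 0) for k in num) for t in tables.values())
    d = sum(sum(t.get(k, 0) for k in den) for t in tables.values())
    if d == 0:
        raise ValueError("empty denominator set")
    p = n / d
    return p, round_half_up(100.0 * p)


@dataclass
class RegionComparison:
    """Two-group comparison of per-collection proportions."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    flavor: str = "welch"
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    @property
    def letters(self) -> tuple[str, str]:
        """Significance letters: differing letters mean p < alpha."""
        return ("a", "b") if self.significant else ("a", "a")


def compare_regions(
    summary: FrequencySummary,
    group_a: Iterable[str],
    group_b: Iterable[str],
    flavor: str = "welch",
    alpha: float = 0.05,
) -> RegionComparison:
    """Two-sided t-test comparing two groups of collections.

    Welch's unequal-variance t (default) or pooled-variance Student's t.
    Both groups need >= 2 collections.  Degenerate identical groups (zero
    pooled standard error, zero mean difference) report t = 0, p = 1.
    """
    ga = tuple(group_a)
    gb = tuple(group_b)
    missing = [g for g in ga + gb if g not in summary.per_collection]
    if missing:
        raise KeyError(f"collections absent from summary: {missing}")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 collections for a t-test")
    a = np.array([summary.per_collection[g] for g in ga])
    b = np.array([summary.per_collection[g] for g in gb])
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
        df = float(len(a) + len(b) - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=(flavor == "student"))
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return RegionComparison(
        group_a=ga,
        group_b=gb,
        t=t,
        df=df,
        p=p,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        flavor=flavor,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Packaged count fixtures (observed counts for the 13 African collections)


def _read_fixture(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("fawhap.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_coib_counts() -> dict[str, dict[str, int]]:
    """Observed COIB haplotype counts per collection (packaged fixture)."""
    df = _read_fixture("coib_haplotype_counts.tsv").set_index("collection")
    return {lab: row.astype(int).to_dict() for lab, row in df.iterrows()}


def load_tpie4_counts() -> dict[str, CollectionCounts]:
    """Observed TpiE4 genotype-class counts per collection (packaged fixture)."""
    df = _read_fixture("tpie4_genotype_counts.tsv").set_index("collection")
    out = {}
    for lab, row in df.iterrows():
        counts = {k: int(row[k]) for k in TPIE4_CLASSES}
        out[lab] = CollectionCounts(
            collection_label=lab,
            source_type=row["source_type"],
            n_specimens_total=sum(counts.values()),
            tpie4_counts=counts,
        )
    return out
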