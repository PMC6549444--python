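"""Synthetic specimen generator with the statistical structure the
pipeline assumes.

Emulates a field collection: each specimen has a sex (pheromone-trap
collections are all male; larval collections draw from a configurable sex
ratio, default 1:1), one (female, ZW) or two (male, ZZ) Z-linked Tpi
alleles drawn independently from the collection's allele-frequency vector
(random mating), and a single maternally inherited COIB haplotype.  Male
heterozygotes are emitted as one Sanger-style consensus sequence with an
IUPAC ambiguity code at every site where the two alleles differ —
exactly the overlapping-chromatograph signal the classifier decodes.

Mito-nuclear coupling is a single discordance probability: the
specimen's COI strain class equals the strain of its first-drawn Tpi
allele, flipped with probability ``discordance``; ``coupling =
"independent"`` instead draws the COIB haplotype straight from its
frequency vector.  Sequences are constructed by editing the panel's
segment references at diagnostic sites (plus indel features); the
pipeline reads only those positions, so no sequence evolution is
simulated.

Defaults mirror the observed continental picture: allele frequencies
(Ca1 0.59, Ca2 0.31, Ra1 0.10 on a chromosome basis; COI-CS ~0.35)
taken from the packaged count fixtures, independent mito-nuclear draws
(the markers are effectively decoupled across most of the continent), a
1:1 sex ratio and a 5% per-marker sequencing failure rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import classify_specimen
from .iupac import union_code
from .panel import MarkerPanel, default_panel
from .popfreq import (
    TPI_ALLELES,
    adjust_tpi_counts,
    tabulate_collection,
)

DEFAULT_TPI_FREQS = {"Ca1": 0.59, "Ca2": 0.31, "Ra1": 0.10}
DEFAULT_COIB_FREQS = {
    "COI-CSa1": 0.33,
    "COI-CSa2": 0.01,
    "COI-RSa1": 0.62,
    "COI-RSa2": 0.03,
    "COI-RSa3": 0.005,
    "COI-RSa4": 0.005,
}
SEGMENTS = ("COIB", "TpiE4", "TpiI4")


@dataclass
class CollectionConfig:
    """Stated world for one simulated collection."""

    label: str
    n: int
    source_type: str = "larva"  # "male_trap" | "larva"
    tpi_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TPI_FREQS)
    )
    coib_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COIB_FREQS)
    )
    coupling: str = "independent"  # "independent" | "discordance"
    discordance: float = 0.0  # P(COI strain disagrees with Tpi strain)
    sex_ratio: float = 0.5  # male fraction for larval collections
    failure_rate: float | dict[str, float] = 0.05  # sequencing failure,
    # either one probability for all markers or {segment: probability}
    site_error_rate: float = 0.0  # per-base substitution error

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.source_type not in ("male_trap", "larva"):
            raise ValueError(f"unknown source_type {self.source_type!r}")
        for name, freqs in (("tpi", self.tpi_freqs), ("coib", self.coib_freqs)):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} frequencies sum to {total}, not 1")
            if any(p < 0 for p in freqs.values()):
                raise ValueError(f"{name} frequencies must be nonnegative")
        failures = (
            list(self.failure_rate.values())
            if isinstance(self.failure_rate, dict)
            else [self.failure_rate]
        )
        for p in (self.discordance, self.sex_ratio, self.site_error_rate,
                  *failures):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.coupling not in ("independent", "discordance"):
            raise ValueError(f"unknown coupling {self.coupling!r}")


@dataclass
class SimConfig:
    collections: list[CollectionConfig]
    seed: int = 0


@dataclass
class SpecimenTruth:
    specimen_id: str
    sex: str  # "male" | "female"
    tpi_alleles: tuple[str, ...]  # one (female) or two (male)
    coib_haplotype: str


@dataclass
class SimTruth:
    """Latent state behind one simulated collection."""

    specimens: list[SpecimenTruth]
    allele_counts: dict[str, int]  # realized Z-chromosome counts

    @property
    def allele_freqs(self) -> dict[str, float]:
        total = sum(self.allele_counts.values())
        return {a: c / total for a, c in self.allele_counts.items()}


@dataclass
class SimulatedCollection:
    config: CollectionConfig
    records: dict[str, list[tuple[str, str]]]  # segment -> [(id, seq)]
    metadata: list[dict[str, str]]
    truth: SimTruth


def _draw(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    labels = sorted(freqs)
    probs = np.array([freqs[k] for k in labels])
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    for i in np.nonzero(rng.random(len(arr)) < rate)[0]:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def _consensus(a: str, b: str) -> str:
    """IUPAC merge of two same-length allele sequences."""
    if len(a) != len(b):
        # indel-differing alleles: merge over the shared prefix length;
        # chromatogram-style mixed-length signal is out of scope
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
    return "".join(x if x == y else union_code(x, y) for x, y in zip(a, b))


def _intron_for(panel: MarkerPanel, exon_hap: str) -> str:
    linked = sorted(
        h.label
        for h in panel.haplotypes_for("TpiI4")
        if h.exon_link == exon_hap and not h.indel_features
    )
    if not linked:
        raise ValueError(f"no indel-free TpiI4 haplotype linked to {exon_hap}")
    return linked[0]


def simulate_collection(
    cfg: CollectionConfig,
    seed: int,
    panel: MarkerPanel | None = None,
) -> SimulatedCollection:
    """Simulate one collection: FASTA records per marker, metadata, truth.

    Fully reproducible from (cfg, seed).  Markers that fail sequencing
    are simply absent from the corresponding record list.
    """
    cfg.validate()
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    strain_of = {a: panel.haplotypes[f"Tpi{a}"].strain for a in TPI_ALLELES}
    tpie4_seq = {
        a: panel.haplotype_sequence(f"Tpi{a}") for a in cfg.tpi_freqs
    }
    intron_label = {a: _intron_for(panel, f"Tpi{a}") for a in cfg.tpi_freqs}
    intron_seq = {
        a: panel.haplotype_sequence(intron_label[a]) for a in cfg.tpi_freqs
    }
    coib_seq = {h: panel.haplotype_sequence(h) for h in cfg.coib_freqs}
    coib_strain = {h: panel.haplotypes[h].strain for h in cfg.coib_freqs}

    records: dict[str, list[tuple[str, str]]] = {s: [] for s in SEGMENTS}
    metadata: list[dict[str, str]] = []
    specimens: list[SpecimenTruth] = []
    allele_counts = {a: 0 for a in cfg.tpi_freqs}

    for i in range(cfg.n):
        sid = f"{cfg.label}_{i + 1:04d}"
        if cfg.source_type == "male_trap":
            sex = "male"
        else:
            sex = "male" if rng.random() < cfg.sex_ratio else "female"
        n_alleles = 2 if sex == "male" else 1
        alleles = tuple(_draw(rng, cfg.tpi_freqs) for _ in range(n_alleles))
        for a in alleles:
            allele_counts[a] += 1

        if cfg.coupling == "independent":
            mito = _draw(rng, cfg.coib_freqs)
        else:
            target = strain_of[alleles[0]]
            if rng.random() < cfg.discordance:
                target = "rice" if target == "corn" else "corn"
            pool = {
                h: p for h, p in cfg.coib_freqs.items()
                if coib_strain[h] == target and p > 0
            } or cfg.coib_freqs
            mito = _draw(rng, pool)
        specimens.append(SpecimenTruth(sid, sex, alleles, mito))
        metadata.append(
            {
                "specimen_id": sid,
                "collection": cfg.label,
                "source_type": cfg.source_type,
                "country": cfg.label,
                "year": "2017",
                "host_class": "CS-host",
            }
        )

        seqs = {
            "COIB": coib_seq[mito],
            "TpiE4": (
                tpie4_seq[alleles[0]]
                if len(set(alleles)) == 1
                else _consensus(tpie4_seq[alleles[0]], tpie4_seq[alleles[1]])
            ),
            "TpiI4": (
                intron_seq[alleles[0]]
                if len({intron_label[a] for a in alleles}) == 1
                else _consensus(intron_seq[alleles[0]], intron_seq[alleles[1]])
            ),
        }
        for segment, seq in seqs.items():
            fail_p = (
                cfg.failure_rate.get(segment, 0.0)
                if isinstance(cfg.failure_rate, dict)
                else cfg.failure_rate
            )
            if rng.random() < fail_p:
                continue
            records[segment].append((sid, _mutate(seq, cfg.site_error_rate, rng)))

    return SimulatedCollection(
        config=cfg,
        records=records,
        metadata=metadata,
        truth=SimTruth(specimens, allele_counts),
    )


# ---------------------------------------------------------------------------
# End-to-end validation harness


@dataclass
class RecoveryReport:
    """Estimated vs generating frequencies for one simulated collection."""

    collection_label: str
    n_specimens: int
    true_freqs: dict[str, float]  # generating allele frequencies
    realized_freqs: dict[str, float]  # realized chromosome frequencies
    estimated_freqs: dict[str, float]  # adjusted-count estimates
    standard_errors: dict[str, float]
    config_counts: dict[str, int]

    def within(self, k: float = 3.0) -> bool:
        """True if every estimate is within k SE of the generating value."""
        return all(
            abs(self.estimated_freqs[a] - self.true_freqs.get(a, 0.0))
            <= k * max(self.standard_errors[a], 1e-12)
            for a in self.estimated_freqs
        )


def end_to_end_recovery(
    cfg: CollectionConfig,
    seed: int,
    panel: MarkerPanel | None = None,
) -> RecoveryReport:
    """Simulate, classify, tabulate and adjust; compare estimates to truth.

    The adjusted-count allele-frequency estimator divides each allele's
    chromosome count by the collection's total adjusted chromosomes; its
    standard error uses the binomial form sqrt(p(1-p)/n_chromosomes).
    """
    panel = panel or default_panel()
    sim = simulate_collection(cfg, seed, panel)
    by_segment = {
        seg: dict(pairs) for seg, pairs in sim.records.items()
    }
    calls = []
    for meta in sim.metadata:
        sid = meta["specimen_id"]
        calls.append(
            classify_specimen(
                sid,
                {seg: by_segment[seg].get(sid) for seg in SEGMENTS},
                panel,
                collection_label=cfg.label,
                source_type=cfg.source_type,
            )
        )
    counts = tabulate_collection(calls)
    adjusted = adjust_tpi_counts(counts)
    total = adjusted.total_chromosomes
    est = {
        a: (adjusted.raw[a] / total if total else float("nan"))
        for a in TPI_ALLELES
    }
    se = {
        a: (
            (est[a] * (1 - est[a]) / total) ** 0.5
            if total and not np.isnan(est[a])
            else float("nan")
        )
        for a in TPI_ALLELES
    }
    return RecoveryReport(
        collection_label=cfg.label,
        n_specimens=cfg.n,
        true_freqs=dict(cfg.tpi_freqs),
        realized_freqs=sim.truth.allele_freqs,
        estimated_freqs=est,
        standard_errors=se,
        config_counts=dict(counts.config_counts),
    )


def simulate(config: SimConfig, panel: MarkerPanel | None = None) -> list[SimulatedCollection]:
    """Simulate every collection in a config, with per-collection subseeds."""
    panel = panel or default_panel()
    root = np.random.default_rng(config.seed)
    out = []
    for cfg in config.collections:
        sub = int(root.integers(0, 2**31 - 1))
        out.append(simulate_collection(cfg, sub, panel))
    return out
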