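"""Readers and writers for the pipeline's plain-text formats.

Sequences travel as FASTA (record id = specimen id), tabular data as TSV.
Every writer emits a header line documenting its columns.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import SpecimenCall
from .iupac import valid_sequence
from .popfreq import (
    AdjustedCounts,
    CollectionCounts,
    FrequencySummary,
    RegionComparison,
    TPI_ALLELES,
    TPIE4_CLASSES,
)

log = logging.getLogger("fawhap")

METADATA_COLUMNS = (
    "specimen_id", "collection", "source_type", "country", "year", "host_class",
)


def read_sequences(path) -> dict[str, str]:
    """Read a FASTA file into {record id: uppercased sequence}.

    Records containing non-IUPAC characters are rejected individually
    with a logged reason; an empty file is an error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq or not valid_sequence(seq):
            log.warning("rejecting record %s: non-IUPAC characters", rec.id)
            continue
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no valid FASTA records in {path}")
    return records


def write_sequences(path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    return df


def write_metadata(path, rows: Iterable[dict]) -> None:
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)


def write_calls(path, calls: Iterable[SpecimenCall]) -> None:
    pd.DataFrame([c.to_row() for c in calls]).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[SpecimenCall]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        SpecimenCall(
            specimen_id=r["specimen_id"],
            collection_label=r["collection"],
            source_type=r["source_type"],
            coib_haplotype=r["coib_haplotype"],
            coi_strain=r["coi_strain"],
            h_config=r["h_config"],
            tpie4_genotype=r["tpie4_genotype"],
            tpi_strain=r["tpi_strain"],
            tpii4_call=r["tpii4_call"],
            qc_flags=[f for f in r["qc_flags"].split(";") if f],
        )
        for _, r in df.iterrows()
    ]


def write_counts(path, counts: Iterable[CollectionCounts]) -> None:
    rows = []
    for c in counts:
        row = {
            "collection": c.collection_label,
            "source_type": c.source_type,
            "n_specimens": c.n_specimens_total,
        }
        row.update({f"coib_{k}": v for k, v in sorted(c.coib_counts.items())})
        row.update(
            {f"tpie4_{k}": c.tpie4_counts.get(k, 0) for k in TPIE4_CLASSES}
        )
        row.update({f"tpii4_{k}": v for k, v in sorted(c.tpii4_counts.items())})
        row["tpii4_heterozygous"] = c.tpii4_heterozygous
        row.update({f"config_{k}": v for k, v in sorted(c.config_counts.items())})
        rows.append(row)
    pd.DataFrame(rows).fillna(0).to_csv(path, sep="\t", index=False)


def write_adjusted(path, adjusted: Iterable[AdjustedCounts]) -> None:
    rows = [
        {
            "collection": a.collection_label,
            "multiplier": a.multiplier,
            **{f"raw_{k}": a.raw[k] for k in TPI_ALLELES},
            **{f"reported_{k}": a.reported[k] for k in TPI_ALLELES},
            "total_chromosomes": a.total_chromosomes,
        }
        for a in adjusted
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_frequency_summaries(path, summaries: Iterable[FrequencySummary]) -> None:
    rows = []
    for s in summaries:
        for collection, value in s.per_collection.items():
            rows.append(
                {
                    "quantity": s.quantity,
                    "collection": collection,
                    "proportion": value,
                    "mean": s.mean,
                    "sd": s.sd,
                    "pooled": s.pooled,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_comparison(path, comparisons: Iterable[RegionComparison]) -> None:
    rows = [
        {
            "group_a": ",".join(c.group_a),
            "group_b": ",".join(c.group_b),
            "flavor": c.flavor,
            "t": c.t,
            "df": c.df,
            "p": c.p,
            "mean_a": c.mean_a,
            "sd_a": c.sd_a,
            "mean_b": c.mean_b,
            "sd_b": c.sd_b,
            "alpha": c.alpha,
            "letter_a": c.letters[0],
            "letter_b": c.letters[1],
        }
        for c in comparisons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
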