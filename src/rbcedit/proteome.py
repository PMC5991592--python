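"""TMT proteome ratio and filter arithmetic.

Per-protein abundance ratios are the mean of the knockout replicates divided
by the mean of the untransduced-control replicates (two technical replicates
each). The table is filtered at 1% FDR with single-peptide identifications
excluded; percent reductions are reported as integer percent (half-up, as
printed), and the headline summary is the share of membrane/cytoskeletal
proteins with at least a twofold reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError, DataError

MEMBRANE = "membrane_cytoskeletal"
OTHER = "other"


@dataclass(frozen=True)
class ProteinQuant:
    """One protein's replicate abundances and metadata."""

    accession: str
    gene: str
    n_peptides: int
    n_unique: int
    abundance_ko: tuple[float, float]
    abundance_ut: tuple[float, float]
    fdr_q: float
    category: str = OTHER

    def __post_init__(self) -> None:
        if any(a < 0 for a in (*self.abundance_ko, *self.abundance_ut)):
            raise ContractError(f"{self.accession}: negative abundance")
        if not 0 <= self.n_unique <= self.n_peptides:
            raise ContractError(f"{self.accession}: peptide counts inconsistent")
        if not 0.0 <= self.fdr_q <= 1.0:
            raise ContractError(f"{self.accession}: fdr_q outside [0, 1]")
        if self.category not in (MEMBRANE, OTHER):
            raise ContractError(f"{self.accession}: unknown category {self.category!r}")


@dataclass(frozen=True)
class ProteomeConfig:
    fdr_max: float = 0.01
    min_peptides: int = 2
    fold_threshold: float = 2.0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if min(self.fdr_max, self.min_peptides, self.fold_threshold,
               self.n_replicates) <= 0:
            raise ContractError("all ProteomeConfig fields must be positive")

    def to_dict(self) -> dict:
        return {
            "fdr_max": self.fdr_max,
            "min_peptides": self.min_peptides,
            "fold_threshold": self.fold_threshold,
            "n_replicates": self.n_replicates,
        }


def abundance_ratio(q: ProteinQuant) -> float:
    """Mean knockout abundance over mean control abundance."""
    ut = sum(q.abundance_ut) / len(q.abundance_ut)
    if ut <= 0:
        raise DataError(f"{q.accession}: zero control mean, ratio undefined")
    ko = sum(q.abundance_ko) / len(q.abundance_ko)
    return ko / ut


def log2_ratio(q: ProteinQuant) -> float:
    ratio = abundance_ratio(q)
    if ratio == 0:
        return float("-inf")
    return math.log2(ratio)


def percent_reduction(ratio: float) -> int:
    """(1 - ratio) x 100 rounded half-up to integer percent.

    Ratios above 1 give a negative value, i.e. a gain.
    """
    if ratio < 0:
        raise ContractError(f"ratio {ratio} < 0")
    return math.floor((1.0 - ratio) * 100.0 + 0.5)


def filter_proteins(
    table: Iterable[ProteinQuant], cfg: ProteomeConfig
) -> list[ProteinQuant]:
    """Keep records at <= ``fdr_max`` FDR with >= ``min_peptides`` peptides."""
    return [
        q
        for q in table
        if q.fdr_q <= cfg.fdr_max and q.n_peptides >= cfg.min_peptides
    ]


def fraction_reduced(
    table: Sequence[ProteinQuant], cfg: ProteomeConfig, category: str = MEMBRANE
) -> float:
    """Percentage of category records with at least a ``fold_threshold``-fold
    reduction (ratio <= 1/fold_threshold). The table is assumed filtered."""
    members = [q for q in table if q.category == category]
    if not members:
        raise DataError(f"no records in category {category!r}")
    reduced = sum(
        1 for q in members if abundance_ratio(q) <= 1.0 / cfg.fold_threshold
    )
    return 100.0 * reduced / len(members)


QUANT_COLUMNS = [
    "accession", "gene", "n_peptides", "n_unique",
    "ko_rep1", "ko_rep2", "ut_rep1", "ut_rep2", "fdr_q", "category",
]


def read_quant_tsv(path: "str | Path") -> list[ProteinQuant]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(QUANT_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"quant TSV missing columns {sorted(missing)}")
    return [
        ProteinQuant(
            accession=row.accession,
            gene=row.gene,
            n_peptides=int(row.n_peptides),
            n_unique=int(row.n_unique),
            abundance_ko=(float(row.ko_rep1), float(row.ko_rep2)),
            abundance_ut=(float(row.ut_rep1), float(row.ut_rep2)),
            fdr_q=float(row.fdr_q),
            category=row.category,
        )
        for row in frame.itertuples(index=False)
    ]


def write_quant_tsv(table: Iterable[ProteinQuant], path: "str | Path") -> None:
    rows = [
        {
            "accession": q.accession,
            "gene": q.gene,
            "n_peptides": q.n_peptides,
            "n_unique": q.n_unique,
            "ko_rep1": q.abundance_ko[0],
            "ko_rep2": q.abundance_ko[1],
            "ut_rep1": q.abundance_ut[0],
            "ut_rep2": q.abundance_ut[1],
            "fdr_q": q.fdr_q,
            "category": q.category,
        }
        for q in table
    ]
    pd.DataFrame(rows, columns=QUANT_COLUMNS).to_csv(path, sep="\t", index=False)


def ratio_table(
    table: Sequence[ProteinQuant], cfg: ProteomeConfig
) -> pd.DataFrame:
    """Per-protein ratio summary with a ``kept`` flag for the filter."""
    kept = {q.accession for q in filter_proteins(table, cfg)}
    rows = []
    for q in table:
        ratio = abundance_ratio(q)
        rows.append(
            {
                "accession": q.accession,
                "gene": q.gene,
                "ratio": ratio,
                "log2_ratio": log2_ratio(q),
                "percent_reduction": percent_reduction(ratio),
                "category": q.category,
                "kept": q.accession in kept,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "gene", "ratio", "log2_ratio",
            "percent_reduction", "category", "kept",
        ],
    )
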