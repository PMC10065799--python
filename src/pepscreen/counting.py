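"""Peptide abundance tables and variant/reference paired counting."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Tuple, Union

import pandas as pd

from .translation import Mode, PeptideRecord, passes_mode

__all__ = [
    "CountTable",
    "VariantPair",
    "VariantPairList",
    "LibrarySummary",
    "count_peptides",
    "count_paired",
    "summarize_library",
    "load_variant_pairs",
    "write_counts_tsv",
    "read_counts_tsv",
]


@dataclass
class CountTable:
    """Per-sample peptide counts.

    n_total is the total number of peptide-coding reads that passed the
    active filter; it is the denominator of the per-peptide frequency.
    n_total_override carries a pre-filter total when normalization over all
    peptide-coding reads is requested instead.
    """

    sample_id: str
    counts: Counter = field(default_factory=Counter)
    n_total_override: Optional[int] = None

    @property
    def n_total(self) -> int:
        if self.n_total_override is not None:
            return self.n_total_override
        return sum(self.counts.values())

    def __getitem__(self, peptide: str) -> int:
        return self.counts.get(peptide, 0)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class VariantPair:
    pair_name: str
    variant: str
    reference: str


@dataclass
class VariantPairList:
    """Line-aligned variant and reference peptides (defined-library design)."""

    pairs: List[VariantPair]

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)


@dataclass(frozen=True)
class LibrarySummary:
    """Composition summary over the unique peptides of one sample."""

    n_unique: int
    stop_fraction: float


def count_peptides(
    records: Iterable[PeptideRecord],
    mode_filter: Optional[Mode] = None,
    sample_id: str = "",
    total_over: str = "filtered",
) -> CountTable:
    """Exact multiset count of translated peptides from one sample.

    When mode_filter is given, only records passing that classification
    contribute to counts; n_total covers the same filtered set by default,
    or every translated read with total_over="all" (normalization before
    filtering).
    """
    if total_over not in ("filtered", "all"):
        raise ValueError("total_over must be 'filtered' or 'all'")
    table = CountTable(sample_id)
    if mode_filter is None:
        table.counts.update(rec.peptide for rec in records)
    else:
        n_all = 0
        for rec in records:
            n_all += 1
            if passes_mode(rec, mode_filter):
                table.counts[rec.peptide] += 1
        if total_over == "all":
            table.n_total_override = n_all
    return table


def count_paired(table: CountTable, pairs: VariantPairList) -> pd.DataFrame:
    """Side-by-side counts of each variant/reference pair in one sample.

    Peptides absent from the sample count as 0; peptides not in the pair
    list are simply not represented here (they remain in the CountTable).
    """
    rows = [
        {
            "pair_name": p.pair_name,
            "variant": p.variant,
            "reference": p.reference,
            "variant_count": table[p.variant],
            "reference_count": table[p.reference],
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["pair_name", "variant", "reference", "variant_count", "reference_count"])


def summarize_library(table: CountTable) -> LibrarySummary:
    """Number of distinct peptides and the fraction of unique peptides
    containing at least one stop, computed over unique sequences (not
    read-weighted)."""
    if len(table) == 0:
        raise ValueError("cannot summarize an empty count table")
    n_unique = len(table.counts)
    n_stop = sum(1 for pep in table.counts if "*" in pep)
    return LibrarySummary(n_unique=n_unique, stop_fraction=n_stop / n_unique)


def _read_peptide_lines(path: Union[str, Path], expected_length: Optional[int]) -> List[str]:
    peptides = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            # blank/comment lines are rejected, not skipped: the two files
            # must stay line-aligned and silent skipping would hide drift
            if not line or line.startswith("#"):
                raise ValueError(f"{path}:{lineno}: blank or comment line not allowed in pair files")
            if expected_length is not None and len(line) != expected_length:
                raise ValueError(
                    f"{path}:{lineno}: peptide {line!r} has length {len(line)}, expected {expected_length}"
                )
            peptides.append(line)
    return peptides


def load_variant_pairs(
    variant_path: Union[str, Path],
    reference_path: Union[str, Path],
    expected_length: Optional[int] = 11,
    pair_names: Optional[List[str]] = None,
) -> VariantPairList:
    """Load line-aligned variant and reference peptide files.

    Raises a configuration error before any counting if the files differ
    in length or contain blank/comment lines.
    """
    variants = _read_peptide_lines(variant_path, expected_length)
    references = _read_peptide_lines(reference_path, expected_length)
    if len(variants) != len(references):
        raise ValueError(
            f"pair files are not line-aligned: {variant_path} has {len(variants)} lines, "
            f"{reference_path} has {len(references)}"
        )
    if pair_names is None:
        pair_names = [f"pair{i + 1}" for i in range(len(variants))]
    pairs = [VariantPair(n, v, r) for n, v, r in zip(pair_names, variants, references)]
    return VariantPairList(pairs)


def write_counts_tsv(table: CountTable, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["peptide", "count"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: Union[str, Path], sample_id: str = "") -> CountTable:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "count": int})
    table = CountTable(sample_id or Path(path).stem)
    table.counts.update(dict(zip(df["peptide"], df["count"])))
    return table
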