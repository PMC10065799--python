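"""Scoring peptides against a log2-enrichment specificity matrix.

The raw score of a peptide is the mean of its residues' log2 enrichment
values over the variable (non-central) positions; the central tyrosine is
fixed by the library design and is ignored.  Raw scores are min-max
normalized so that the best achievable sequence under the matrix scores 1
and the worst scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple


import pandas as pd

from .pssm import PositionMatrix

__all__ = [
    "PeptideScore",
    "score_peptide",
    "score_extremes",
    "normalize_score",
    "score_peptides",
    "predict_variant_effect",
    "best_sequence",
]


@dataclass(frozen=True)
class PeptideScore:
    peptide: str
    raw: float
    normalized: Optional[float]
    n_scored: int


def _check_matrix(matrix: PositionMatrix) -> None:
    if matrix.layer != "log2_enrichment":
        raise ValueError(f"scoring requires a log2_enrichment matrix, got {matrix.layer!r}")


def _variable_positions(matrix: PositionMatrix) -> List[int]:
    return [p for p in matrix.positions if p != 0]


def score_peptide(peptide: str, matrix: PositionMatrix) -> PeptideScore:
    """Raw score: mean log2 enrichment of the peptide's residues over the
    variable positions (10 for the X5-Y-X5 geometry).

    The peptide must match the matrix width, carry a central Tyr, and
    contain no stop symbol; a residue falling on a missing matrix cell is
    an error naming the cell.
    """
    _check_matrix(matrix)
    positions = matrix.positions
    if len(peptide) != len(positions):
        raise ValueError(f"peptide {peptide!r} has length {len(peptide)}, matrix expects {len(positions)}")
    if "*" in peptide:
        raise ValueError(f"peptide {peptide!r} contains a stop symbol and cannot be scored")
    center_idx = positions.index(0)
    if peptide[center_idx] != "Y":
        raise ValueError(f"peptide {peptide!r}: central residue must be Y, got {peptide[center_idx]!r}")
    total = 0.0
    n_scored = 0
    for idx, pos in enumerate(positions):
        if pos == 0:
            continue
        residue = peptide[idx]
        value = matrix.values.at[residue, pos]
        if pd.isna(value):
            raise ValueError(f"matrix cell ({residue!r}, position {pos:+d}) is missing")
        total += float(value)
        n_scored += 1
    return PeptideScore(peptide, raw=total / n_scored, normalized=None, n_scored=n_scored)


def score_extremes(matrix: PositionMatrix) -> Tuple[float, float]:
    """(best_raw, worst_raw): means of the per-column maxima and minima over
    the variable positions, excluding the stop row."""
    _check_matrix(matrix)
    body = matrix.values.drop(index="*")[_variable_positions(matrix)]
    if body.isna().all(axis=0).any():
        cols = [c for c in body.columns if body[c].isna().all()]
        raise ValueError(f"degenerate matrix: variable positions {cols} entirely missing")
    # sequential accumulation in position order, matching score_peptide, so
    # the best/worst sequences normalize to exactly 1 and 0
    maxima = body.max(axis=0, skipna=True)
    minima = body.min(axis=0, skipna=True)
    best_total = 0.0
    worst_total = 0.0
    for pos in body.columns:
        best_total += float(maxima[pos])
        worst_total += float(minima[pos])
    n = len(body.columns)
    return best_total / n, worst_total / n


def normalize_score(raw: float, extremes: Tuple[float, float]) -> float:
    """Min-max normalization onto [0, 1]: 0 = worst possible sequence,
    1 = best possible sequence under the matrix."""
    best, worst = extremes
    if best <= worst:
        raise ValueError("constant matrix: best and worst scores coincide, cannot normalize")
    return (raw - worst) / (best - worst)


def score_peptides(peptides: Iterable[str], matrix: PositionMatrix) -> pd.DataFrame:
    """Score a peptide list; returns raw and normalized scores per peptide."""
    extremes = score_extremes(matrix)
    rows = []
    for pep in peptides:
        s = score_peptide(pep, matrix)
        rows.append({"peptide": pep, "raw_score": s.raw, "normalized_score": normalize_score(s.raw, extremes)})
    return pd.DataFrame(rows, columns=["peptide", "raw_score", "normalized_score"]).set_index("peptide")


def best_sequence(matrix: PositionMatrix, exclude: Iterable[str] = ()) -> str:
    """Sequence taking the maximum-enrichment residue at every variable
    position (stop row excluded; `exclude` drops further residues, e.g.
    'Y' when designing consensus substrates) with Tyr fixed at the center."""
    _check_matrix(matrix)
    drop = ["*"] + [r for r in exclude if r in matrix.values.index]
    body = matrix.values.drop(index=drop)
    out = []
    for pos in matrix.positions:
        out.append("Y" if pos == 0 else str(body[pos].idxmax(skipna=True)))
    return "".join(out)


def predict_variant_effect(variant: str, reference: str, matrix: PositionMatrix) -> float:
    """Signed difference of normalized scores (variant - reference); positive
    values predict a gain of function."""
    if variant == reference:
        warnings.warn("variant and reference peptides are identical; delta is 0", stacklevel=2)
        return 0.0
    extremes = score_extremes(matrix)
    v = normalize_score(score_peptide(variant, matrix).raw, extremes)
    r = normalize_score(score_peptide(reference, matrix).raw, extremes)
    return v - r
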