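"""Position-specific specificity matrices (21 residues x 11 positions).

Rows are the 20 amino acids in alphabetical one-letter order with the stop
symbol '*' as the 21st row; columns are peptide positions -5..+5 with the
phospho-acceptor tyrosine at 0.  Three counting modes reflect how reads are
admitted:

* ``nostop``    — central Tyr and no stop codons (standard screens),
* ``full``      — every expected-length sequence (stop-depletion analysis),
* ``one_amber`` — central Tyr and exactly one Amber stop (Amber-suppression
  screens, where TAG encodes a non-canonical amino acid).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List, Optional, Union

import numpy as np
import pandas as pd

from .translation import Mode, PeptideRecord, passes_mode

__all__ = [
    "AA_ORDER",
    "ROW_ORDER",
    "PositionMatrix",
    "position_counts",
    "position_frequencies",
    "position_enrichment",
    "average_matrices",
    "write_matrix_csv",
    "read_matrix_csv",
]

AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY")
ROW_ORDER = AA_ORDER + ["*"]
N_POSITIONS = 11
POSITIONS = list(range(-(N_POSITIONS // 2), N_POSITIONS // 2 + 1))  # -5..+5

# ASCII byte -> row index lookup for fast tallying
_ROW_OF_BYTE = np.full(256, -1, dtype=np.int64)
for _i, _aa in enumerate(ROW_ORDER):
    _ROW_OF_BYTE[ord(_aa)] = _i


def _position_labels(positions: List[int]) -> List[str]:
    return [f"{p:+d}" if p > 0 else str(p) for p in positions]


@dataclass(frozen=True)
class PositionMatrix:
    """One layer (counts / frequency / log2_enrichment) of a specificity
    matrix, as a labelled 21x11 DataFrame."""

    values: pd.DataFrame
    layer: str  # counts | frequency | log2_enrichment
    mode: Mode
    sample_id: str = ""

    def __post_init__(self) -> None:
        if list(self.values.index) != ROW_ORDER:
            raise ValueError("matrix rows must be the 20 amino acids then '*'")

    @property
    def positions(self) -> List[int]:
        return list(self.values.columns)

    @property
    def central(self) -> int:
        return 0


def position_counts(
    records: Iterable[PeptideRecord],
    mode: Mode,
    sample_id: str = "",
    exclude_cys: bool = False,
    exclude_noncentral_tyr: bool = False,
) -> PositionMatrix:
    """Tally residue occurrences per position over qualifying peptides.

    Each qualifying peptide adds 1 to the (residue, position) cell at all
    11 positions; non-qualifying peptides contribute nothing.  The optional
    exclusions drop Cys-containing or multi-Tyr sequences entirely, for
    screens where oxidation or multi-acceptor signal is a concern.
    """
    peptides = [rec.peptide for rec in records if passes_mode(rec, mode)]
    if exclude_cys:
        peptides = [p for p in peptides if "C" not in p]
    if exclude_noncentral_tyr:
        center = len(peptides[0]) // 2 if peptides else 0
        peptides = [p for p in peptides if p.count("Y") == (1 if p[center] == "Y" else 0)]
    if not peptides:
        raise ValueError(f"no records qualify under mode {mode!r}")
    width = len(peptides[0])
    arr = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(peptides), width)
    rows = _ROW_OF_BYTE[arr]
    counts = np.zeros((len(ROW_ORDER), width), dtype=np.int64)
    for col in range(width):
        counts[:, col] = np.bincount(rows[:, col], minlength=len(ROW_ORDER))
    positions = list(range(-(width // 2), width // 2 + 1))
    df = pd.DataFrame(counts, index=ROW_ORDER, columns=positions)
    return PositionMatrix(df, layer="counts", mode=mode, sample_id=sample_id)


def pool_counts(matrices: List[PositionMatrix]) -> PositionMatrix:
    """Sum replicate counts matrices cell-wise (the pooled-counts
    alternative to averaging per-replicate log2 matrices)."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices:
        if m.layer != "counts" or m.mode != first.mode:
            raise ValueError("pooling requires counts matrices of one mode")
    total = sum(m.values.to_numpy() for m in matrices)
    df = pd.DataFrame(total, index=first.values.index, columns=first.values.columns)
    return replace(first, values=df, sample_id="pooled")


def position_frequencies(m: PositionMatrix) -> PositionMatrix:
    """Column-normalize a counts matrix: cell / column total."""
    if m.layer != "counts":
        raise ValueError(f"expected a counts matrix, got layer {m.layer!r}")
    totals = m.values.sum(axis=0)
    if (totals == 0).any():
        empty = [c for c in m.values.columns if totals[c] == 0]
        raise ValueError(f"zero column total at positions {empty}")
    return replace(m, values=m.values / totals, layer="frequency")


def _structural_mask(mode: Mode, index, columns) -> pd.DataFrame:
    """Cells that are undefined under a mode (always-zero by construction),
    to be marked missing on the log2 layer."""
    mask = pd.DataFrame(False, index=index, columns=columns)
    if 0 in columns:
        if mode in ("nostop", "one_amber"):
            # central position is fixed Tyr; other residues never occur
            mask.loc[[r for r in index if r != "Y"], 0] = True
    if mode == "nostop":
        mask.loc["*", :] = True
    return mask


def position_enrichment(
    selected: PositionMatrix,
    input: PositionMatrix,
    pseudo_freq: float = 1e-4,
) -> PositionMatrix:
    """Log2 ratio of selected over input frequencies, cell-wise.

    log2((f_sel + pseudo_freq) / (f_in + pseudo_freq)); the small frequency
    pseudocount keeps unobserved residue/position cells finite.  Cells that
    are undefined in-mode (the '*' row in nostop mode, central non-Tyr) are
    set to NaN.
    """
    for m, name in ((selected, "selected"), (input, "input")):
        if m.layer != "frequency":
            raise ValueError(f"{name} matrix must be a frequency layer, got {m.layer!r}")
    if selected.mode != input.mode:
        raise ValueError(f"mode mismatch: {selected.mode!r} vs {input.mode!r}")
    if selected.values.shape != input.values.shape or list(selected.values.columns) != list(input.values.columns):
        raise ValueError("matrix shape/position mismatch")
    if pseudo_freq < 0:
        raise ValueError("pseudo_freq must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2((selected.values + pseudo_freq) / (input.values + pseudo_freq))
    mask = _structural_mask(selected.mode, log2.index, log2.columns)
    log2 = log2.mask(mask)
    return PositionMatrix(log2, layer="log2_enrichment", mode=selected.mode,
                          sample_id=selected.sample_id)


def average_matrices(matrices: List[PositionMatrix]) -> PositionMatrix:
    """Cell-wise arithmetic mean of replicate matrices, ignoring missing
    cells; the replicate-averaged heatmap layer."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.mode != first.mode or m.layer != first.layer:
            raise ValueError("all matrices must share mode and layer")
        if list(m.values.columns) != list(first.values.columns):
            raise ValueError("all matrices must share positions")
    stacked = np.stack([m.values.to_numpy(dtype=float) for m in matrices])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    df = pd.DataFrame(mean, index=first.values.index, columns=first.values.columns)
    return replace(first, values=df, sample_id="mean")


def write_matrix_csv(m: PositionMatrix, path: Union[str, Path]) -> None:
    """Write a labelled matrix CSV with layer/mode recorded in a comment."""
    with open(path, "w") as handle:
        handle.write(f"# layer={m.layer} mode={m.mode} sample={m.sample_id}\n")
        out = m.values.copy()
        out.columns = _position_labels(list(out.columns))
        out.index.name = "residue"
        out.to_csv(handle)


def read_matrix_csv(path: Union[str, Path]) -> PositionMatrix:
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing matrix header comment")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        df = pd.read_csv(handle, index_col=0)
    df.columns = [int(c) for c in df.columns]
    return PositionMatrix(df, layer=meta["layer"], mode=meta["mode"], sample_id=meta.get("sample", ""))
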