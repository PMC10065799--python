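"""Synthetic peptide-display screens with known ground truth, plus library
oligo design.

The generative model is a single round of selection: input reads are drawn
uniformly (multinomially) from the library pool; selected reads are drawn
with probability proportional to exp(strength * score), where score is the
peptide's mean truth-matrix log2 preference over the variable positions.
Peptides carrying a premature stop are removed from the selectable pool
with probability ``amber_termination_prob`` — a truncated peptide is not
displayed on the cell surface, so it cannot be captured, except for the
read-through/suppression leakage that the complement of that probability
represents.  Each emitted read carries the fixed amplicon flanks so the
whole pipeline (trim -> translate -> count -> matrices) can run on
simulator output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .pssm import AA_ORDER, ROW_ORDER, N_POSITIONS, PositionMatrix, _ROW_OF_BYTE
from .seqio import DEFAULT_FIVE_PRIME, DEFAULT_THREE_PRIME, MergedRead
from .translation import CODON_TABLE

__all__ = [
    "ScreenTruth",
    "OligoDesign",
    "ECOLI_CODON_USAGE",
    "MOST_FREQUENT_CODON",
    "SFII_SITE",
    "nns_codons",
    "nns_amino_acids",
    "amber_codon_fraction",
    "prob_at_least_one_amber",
    "sample_nns_library",
    "random_truth_matrix",
    "truth_scores",
    "simulate_selection",
    "reverse_translate",
    "design_library_oligos",
    "write_reads",
]

#: E. coli synonymous codons in decreasing usage order (K-12 usage table);
#: the first entry per amino acid is the most frequently used codon.
ECOLI_CODON_USAGE: Dict[str, List[str]] = {
    "A": ["GCG", "GCC", "GCA", "GCT"],
    "C": ["TGC", "TGT"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGC", "GGT", "GGG", "GGA"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["CTG", "TTA", "TTG", "CTT", "CTC", "CTA"],
    "M": ["ATG"],
    "N": ["AAC", "AAT"],
    "P": ["CCG", "CCA", "CCT", "CCC"],
    "Q": ["CAG", "CAA"],
    "R": ["CGC", "CGT", "CGG", "CGA", "AGA", "AGG"],
    "S": ["AGC", "TCG", "AGT", "TCC", "TCT", "TCA"],
    "T": ["ACC", "ACG", "ACT", "ACA"],
    "V": ["GTG", "GTT", "GTC", "GTA"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}

MOST_FREQUENT_CODON: Dict[str, str] = {aa: codons[0] for aa, codons in ECOLI_CODON_USAGE.items()}

#: SfiI recognition site (degenerate): GGCCNNNNNGGCC
SFII_SITE = "GGCCNNNNNGGCC"

_NNS_THIRD = "GC"
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# NNS degenerate-codon statistics

def nns_codons() -> List[str]:
    """All 32 NNS codons (N = A,C,G,T; S = G,C)."""
    return [a + b + s for a in _BASES for b in _BASES for s in _NNS_THIRD]


def nns_amino_acids() -> set:
    """Amino acids encodable by an NNS codon (all 20; the only stop is TAG)."""
    return {CODON_TABLE[c] for c in nns_codons()} - {"*"}


def amber_codon_fraction() -> float:
    """Fraction of NNS codons that are the Amber stop TAG (= 1/32)."""
    codons = nns_codons()
    return sum(1 for c in codons if c == "TAG") / len(codons)


def prob_at_least_one_amber(n_codons: int = 10) -> float:
    """Probability that n independent NNS codons contain >= 1 TAG:
    1 - (31/32)**n; ~0.272 for the ten variable codons."""
    return 1.0 - (1.0 - amber_codon_fraction()) ** n_codons


# ---------------------------------------------------------------------------
# Library sampling and ground truth

def sample_nns_library(n: int, seed: Union[int, np.random.Generator]) -> List[str]:
    """Draw n random X5-Y-X5 coding regions: five NNS codons, the fixed
    central TAT, five NNS codons (33 nt).  Deterministic under seed."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_var = N_POSITIONS - 1  # 10 variable codons
    first = rng.choice(list(_BASES), size=(n, n_var))
    second = rng.choice(list(_BASES), size=(n, n_var))
    third = rng.choice(list(_NNS_THIRD), size=(n, n_var))
    out = []
    for i in range(n):
        codons = [first[i, j] + second[i, j] + third[i, j] for j in range(n_var)]
        out.append("".join(codons[:5]) + "TAT" + "".join(codons[5:]))
    return out


def random_truth_matrix(
    seed: Union[int, np.random.Generator],
    low: float = -2.0,
    high: float = 2.0,
) -> PositionMatrix:
    """A random ground-truth log2 preference matrix: entries uniform in
    [low, high] for the 20 amino acids at the 10 variable positions; the
    central column and the stop row are zero (the center is fixed Tyr and
    premature termination is modelled separately)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = list(range(-(N_POSITIONS // 2), N_POSITIONS // 2 + 1))
    values = np.zeros((len(ROW_ORDER), N_POSITIONS))
    var_cols = [i for i, p in enumerate(positions) if p != 0]
    values[: len(AA_ORDER), var_cols] = rng.uniform(low, high, size=(len(AA_ORDER), len(var_cols)))
    df = pd.DataFrame(values, index=ROW_ORDER, columns=positions)
    return PositionMatrix(df, layer="log2_enrichment", mode="full", sample_id="truth")


@dataclass(frozen=True)
class ScreenTruth:
    """Ground truth and sampling parameters for one synthetic screen."""

    truth_matrix: PositionMatrix
    selection_strength: float = 1.0
    depth_input: int = 100_000
    depth_selected: int = 100_000
    seed: int = 0
    amber_termination_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.depth_input <= 0 or self.depth_selected <= 0:
            raise ValueError("read depths must be positive")
        if not 0.0 <= self.amber_termination_prob <= 1.0:
            raise ValueError("amber_termination_prob must be in [0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")


def _translate_pool(library: Sequence[str]) -> List[str]:
    return ["".join(CODON_TABLE[dna[i : i + 3]] for i in range(0, len(dna), 3)) for dna in library]


def truth_scores(peptides: Sequence[str], matrix: PositionMatrix) -> np.ndarray:
    """Mean truth-matrix value of each peptide over the variable positions
    (vectorized row lookup; the stop row scores stop residues)."""
    positions = matrix.positions
    width = len(positions)
    arr = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8).reshape(len(peptides), width)
    rows = _ROW_OF_BYTE[arr]
    if (rows < 0).any():
        raise ValueError("peptide contains a residue outside the 20-AA + '*' alphabet")
    M = matrix.values.to_numpy(dtype=float)
    var_cols = np.array([i for i, p in enumerate(positions) if p != 0])
    cell_values = M[rows[:, var_cols], var_cols[None, :]]
    return cell_values.mean(axis=1)


def simulate_selection(
    library: Sequence[str],
    truth: ScreenTruth,
    five_prime: str = DEFAULT_FIVE_PRIME,
    three_prime: str = DEFAULT_THREE_PRIME,
) -> Tuple[List[MergedRead], List[MergedRead]]:
    """Simulate one selection round over a library of coding regions.

    Returns (input_reads, selected_reads) as flank-carrying MergedReads.
    Input reads are a uniform multinomial draw from the library; selected
    reads are drawn with probability proportional to
    exp(selection_strength * truth score), after each stop-containing
    member has been removed from the selectable pool with probability
    amber_termination_prob.  Fully reproducible from truth.seed.
    """
    if not library:
        raise ValueError("library is empty")
    rng = np.random.default_rng(truth.seed)
    n = len(library)
    peptides = _translate_pool(library)
    scores = truth_scores(peptides, truth.truth_matrix)

    weights = np.exp(truth.selection_strength * scores)
    has_stop = np.array(["*" in p for p in peptides])
    if truth.amber_termination_prob > 0 and has_stop.any():
        removed = rng.random(n) < truth.amber_termination_prob
        weights[has_stop & removed] = 0.0
    total = weights.sum()
    if total <= 0:
        raise ValueError("selectable pool is empty (all members removed)")

    idx_input = rng.choice(n, size=truth.depth_input, replace=True)
    idx_selected = rng.choice(n, size=truth.depth_selected, replace=True, p=weights / total)

    def _reads(indices: np.ndarray, prefix: str) -> List[MergedRead]:
        reads = []
        for k, i in enumerate(indices):
            seq = five_prime + library[i] + three_prime
            reads.append(MergedRead(f"{prefix}_{k:07d}", seq, "I" * len(seq)))
        return reads

    return _reads(idx_input, "input"), _reads(idx_selected, "selected")


# ---------------------------------------------------------------------------
# Oligo design

@dataclass(frozen=True)
class OligoDesign:
    peptide: str
    dna: str
    gc_fraction: float
    forbidden_site_free: bool
    feasible: bool
    note: str = ""


def _gc_fraction(dna: str) -> float:
    return (dna.count("G") + dna.count("C")) / len(dna)


def _motif_regex(motif: str) -> re.Pattern:
    return re.compile(motif.replace("N", "[ACGT]"))


def reverse_translate(peptide: str, codon_table: Optional[Dict[str, str]] = None) -> str:
    """Peptide to DNA using the most frequently used E. coli codon per
    residue (or a supplied single-codon mapping)."""
    table = MOST_FREQUENT_CODON if codon_table is None else codon_table
    try:
        return "".join(table[aa] for aa in peptide)
    except KeyError as exc:
        raise ValueError(f"cannot reverse-translate residue {exc} in {peptide!r}") from exc


def _design_penalty(dna: str, gc_bounds: Tuple[float, float], patterns: List[re.Pattern]) -> float:
    gc = _gc_fraction(dna)
    lo, hi = gc_bounds
    gc_pen = max(0.0, lo - gc) + max(0.0, gc - hi)
    motif_pen = sum(len(p.findall(dna)) for p in patterns)
    return motif_pen + gc_pen


def design_library_oligos(
    peptides: Iterable[str],
    codon_usage: Optional[Dict[str, List[str]]] = None,
    gc_bounds: Tuple[float, float] = (0.30, 0.70),
    forbidden_motifs: Sequence[str] = (SFII_SITE,),
    max_sweeps: int = 10,
) -> List[OligoDesign]:
    """Design coding oligos for defined-library peptides.

    Each peptide is first reverse-translated with the most frequent E. coli
    codon per residue, then synonymous codons are swapped greedily
    (positions left to right, candidate codons in decreasing usage order)
    until the GC fraction lies within gc_bounds and no forbidden motif
    remains, or no swap improves further (reported infeasible, never
    silently dropped).  Translation is preserved by construction.
    """
    usage = ECOLI_CODON_USAGE if codon_usage is None else codon_usage
    patterns = [_motif_regex(m) for m in forbidden_motifs]
    designs = []
    for peptide in peptides:
        codons = [usage[aa][0] for aa in peptide]
        penalty = _design_penalty("".join(codons), gc_bounds, patterns)
        for _ in range(max_sweeps):
            if penalty == 0:
                break
            improved = False
            for i, aa in enumerate(peptide):
                best_codon, best_pen = codons[i], penalty
                for candidate in usage[aa]:
                    if candidate == codons[i]:
                        continue
                    trial = codons.copy()
                    trial[i] = candidate
                    pen = _design_penalty("".join(trial), gc_bounds, patterns)
                    if pen < best_pen:
                        best_codon, best_pen = candidate, pen
                if best_codon != codons[i]:
                    codons[i] = best_codon
                    penalty = best_pen
                    improved = True
            if not improved:
                break
        dna = "".join(codons)
        gc = _gc_fraction(dna)
        site_free = not any(p.search(dna) for p in patterns)
        lo, hi = gc_bounds
        feasible = site_free and lo <= gc <= hi
        note = "" if feasible else (
            f"gc={gc:.3f} outside [{lo}, {hi}]" if site_free else "forbidden motif could not be removed"
        )
        designs.append(OligoDesign(peptide, dna, gc, site_free, feasible, note))
    return designs


# ---------------------------------------------------------------------------
# Read output

def write_reads(reads: Iterable[MergedRead], path, format: str = "fastq") -> int:
    """Write simulated reads as FASTQ (constant quality 'I') or FASTA."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            if format == "fastq":
                qual = read.quality or "I" * len(read.sequence)
                handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            elif format == "fasta":
                handle.write(f">{read.read_id}\n{read.sequence}\n")
            else:
                raise ValueError(f"unknown format {format!r}")
            n += 1
    return n
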