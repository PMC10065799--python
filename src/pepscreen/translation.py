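"""Translation of coding regions into 11-mer peptides with stop provenance.

Stops are rendered as ``'*'``.  The TAG (Amber) codon is tracked separately
from TAA/TGA because, under Amber suppression, TAG encodes a non-canonical
amino acid and one-Amber sequences become analysable; in an NNS library
(third base G or C) Amber is the only reachable stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Literal, Optional, Union

from Bio.Data.CodonTable import standard_dna_table

from .seqio import CodingRegion

__all__ = [
    "PeptideRecord",
    "TranslationDiscard",
    "CODON_TABLE",
    "STOP_CODONS",
    "AMBER",
    "translate_coding_region",
    "translate_regions",
    "classify_peptide",
    "passes_mode",
]

AMBER = "TAG"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

#: Standard genetic code: 64 codons -> amino acid one-letter code or '*'.
CODON_TABLE: dict = dict(standard_dna_table.forward_table)
CODON_TABLE.update({codon: "*" for codon in STOP_CODONS})
assert len(CODON_TABLE) == 64

Mode = Literal["nostop", "full", "one_amber"]
DEFAULT_PEPTIDE_LENGTH = 11


@dataclass(frozen=True)
class PeptideRecord:
    """Translated peptide with per-codon provenance.

    central_is_tyr refers to the phospho-acceptor position (index
    length//2, i.e. position 0 of the -5..+5 coordinate system).
    """

    read_id: str
    peptide: str
    codons: tuple
    n_stop: int
    n_amber: int
    central_is_tyr: bool


@dataclass(frozen=True)
class TranslationDiscard:
    read_id: str
    reason: Literal["wrong-length", "ambiguous-base"]


def translate_coding_region(
    region: CodingRegion,
    expected_length: int = DEFAULT_PEPTIDE_LENGTH,
    codon_table: Optional[dict] = None,
) -> Union[PeptideRecord, TranslationDiscard]:
    """Translate a coding region into a peptide of the expected length.

    Regions whose length differs from 3*expected_length are discarded as
    wrong-length; regions containing bases outside {A,C,G,T} (e.g. N) are
    discarded as ambiguous-base rather than translated to 'X', since the
    counting stages operate on the exact 20-amino-acid + stop alphabet.
    """
    table = CODON_TABLE if codon_table is None else codon_table
    dna = region.dna
    if len(dna) != 3 * expected_length:
        return TranslationDiscard(region.read_id, "wrong-length")
    codons = tuple(dna[i : i + 3] for i in range(0, len(dna), 3))
    try:
        peptide = "".join(table[c] for c in codons)
    except KeyError:
        return TranslationDiscard(region.read_id, "ambiguous-base")
    n_stop = peptide.count("*")
    n_amber = sum(1 for c in codons if c == AMBER)
    central = peptide[expected_length // 2] == "Y"
    return PeptideRecord(region.read_id, peptide, codons, n_stop, n_amber, central)


def translate_regions(
    regions: Iterable[CodingRegion],
    expected_length: int = DEFAULT_PEPTIDE_LENGTH,
    discards: Optional[list] = None,
) -> Iterator[PeptideRecord]:
    """Translate a stream of regions, yielding records and optionally
    collecting TranslationDiscard signals."""
    for region in regions:
        result = translate_coding_region(region, expected_length)
        if isinstance(result, PeptideRecord):
            yield result
        elif discards is not None:
            discards.append(result)


def classify_peptide(rec: PeptideRecord) -> dict:
    """Classification flags used by the three matrix-counting modes.

    nostop_ok:    central tyrosine and no stop codons (standard screens)
    full_ok:      any peptide of the expected length (stop-depletion view)
    one_amber_ok: central tyrosine and exactly one stop which is Amber
                  (Amber-suppression screens, where TAG encodes a
                  non-canonical residue)
    """
    return {
        "nostop_ok": rec.central_is_tyr and rec.n_stop == 0,
        "full_ok": True,
        "one_amber_ok": rec.central_is_tyr and rec.n_stop == 1 and rec.n_amber == 1,
    }


def passes_mode(rec: PeptideRecord, mode: Optional[Mode]) -> bool:
    """Whether a record contributes under the given counting mode."""
    if mode is None or mode == "full":
        return True
    if mode == "nostop":
        return rec.central_is_tyr and rec.n_stop == 0
    if mode == "one_amber":
        return rec.central_is_tyr and rec.n_stop == 1 and rec.n_amber == 1
    raise ValueError(f"unknown mode {mode!r}")
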