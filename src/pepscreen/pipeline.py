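"""Convenience chains over the stage modules: reads -> peptides -> counts ->
enrichment / specificity matrices."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import pandas as pd

from . import counting, enrichment, pssm, seqio, translation

__all__ = ["ScreenResult", "reads_to_records", "run_screen", "replicate_matrices"]


@dataclass
class ScreenResult:
    """Outputs of one selected-vs-input screen analysis."""

    input_counts: counting.CountTable
    selected_counts: counting.CountTable
    log2_matrix: pssm.PositionMatrix
    enrichment_table: Optional[pd.DataFrame]
    trim_stats_input: seqio.TrimStats
    trim_stats_selected: seqio.TrimStats


def reads_to_records(
    reads: Iterable[seqio.MergedRead],
    flanks: seqio.FlankSpec = seqio.FlankSpec(),
    stats: Optional[seqio.TrimStats] = None,
) -> List[translation.PeptideRecord]:
    """Trim flanks and translate a read stream into peptide records."""
    regions = seqio.trim_reads(reads, flanks, stats=stats)
    return list(translation.translate_regions(regions))


def run_screen(
    input_reads: Iterable[seqio.MergedRead],
    selected_reads: Iterable[seqio.MergedRead],
    mode: translation.Mode = "nostop",
    flanks: seqio.FlankSpec = seqio.FlankSpec(),
    pseudo_freq: float = 1e-4,
    with_enrichment_table: bool = False,
    pseudocount: float = 0.5,
) -> ScreenResult:
    """Full single-replicate analysis: trim, translate, count, build the
    log2 specificity matrix (per `mode`), and optionally the per-peptide
    enrichment table."""
    stats_in, stats_sel = seqio.TrimStats(), seqio.TrimStats()
    rec_in = reads_to_records(input_reads, flanks, stats_in)
    rec_sel = reads_to_records(selected_reads, flanks, stats_sel)

    counts_in = counting.count_peptides(rec_in, mode_filter=mode, sample_id="input")
    counts_sel = counting.count_peptides(rec_sel, mode_filter=mode, sample_id="selected")

    m_in = pssm.position_frequencies(pssm.position_counts(rec_in, mode, "input"))
    m_sel = pssm.position_frequencies(pssm.position_counts(rec_sel, mode, "selected"))
    log2_matrix = pssm.position_enrichment(m_sel, m_in, pseudo_freq=pseudo_freq)

    table = None
    if with_enrichment_table:
        table = enrichment.enrichment_scores(counts_sel, counts_in, pseudocount=pseudocount)

    return ScreenResult(counts_in, counts_sel, log2_matrix, table, stats_in, stats_sel)


def replicate_matrices(results: List[ScreenResult]) -> pssm.PositionMatrix:
    """Average the log2 matrices of replicate screens."""
    return pssm.average_matrices([r.log2_matrix for r in results])
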