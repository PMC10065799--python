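"""Per-peptide frequencies, selected-vs-input enrichment scores, and
replicate aggregation.

The enrichment score of a peptide is

    f = n_peptide / n_total          (frequency within a sample)
    E = f_selected / f_input         (selected over input)

E > 1 means the peptide was preferentially phosphorylated/bound and
captured during selection.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .counting import CountTable

__all__ = [
    "peptide_frequency",
    "enrichment_scores",
    "aggregate_replicates",
]


def peptide_frequency(table: CountTable) -> pd.Series:
    """Frequency of every peptide in the sample: f = n_peptide / n_total.

    Frequencies sum to 1 over the counted peptides.
    """
    n_total = table.n_total
    if n_total == 0:
        raise ValueError(f"sample {table.sample_id!r}: n_total is 0, cannot compute frequencies")
    return pd.Series(dict(table.counts), dtype=float, name="frequency") / n_total


def enrichment_scores(
    selected: CountTable,
    input: CountTable,
    pseudocount: float = 0.5,
    universe: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-peptide enrichment table over the union of both samples' peptides
    (or a supplied library universe).

    The raw enrichment column E = f_selected / f_input is computed without
    any pseudocount, for fidelity to the defining ratio; peptides with zero
    input counts are flagged `zero_input` and carry E = NaN.  The
    log2_enrichment column adds `pseudocount` to the raw counts of every
    universe member in both samples and recomputes the frequencies, so the
    logarithm is always finite.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if selected.n_total == 0 and input.n_total == 0:
        raise ValueError("both samples are empty")
    if universe is None:
        peptides = sorted(set(selected.counts) | set(input.counts))
    else:
        peptides = list(universe)
    if not peptides:
        raise ValueError("empty peptide universe")

    n_in = np.array([input[p] for p in peptides], dtype=float)
    n_sel = np.array([selected[p] for p in peptides], dtype=float)
    # pre-filter totals (normalize-before-filtering) take precedence when set
    tot_in = float(input.n_total_override) if input.n_total_override is not None else n_in.sum()
    tot_sel = float(selected.n_total_override) if selected.n_total_override is not None else n_sel.sum()
    if tot_in == 0 or tot_sel == 0:
        raise ValueError("a sample has zero reads over the chosen universe")

    f_in = n_in / tot_in
    f_sel = n_sel / tot_sel
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.where(f_in > 0, f_sel / f_in, np.nan)

    # pseudocount applies to the log2 column only, added to raw counts of
    # every universe member, then frequencies are recomputed
    pc = pseudocount
    f_in_pc = (n_in + pc) / (tot_in + pc * len(peptides)) if pc > 0 else f_in
    f_sel_pc = (n_sel + pc) / (tot_sel + pc * len(peptides)) if pc > 0 else f_sel
    with np.errstate(divide="ignore", invalid="ignore"):
        log2E = np.log2(f_sel_pc / f_in_pc)

    return pd.DataFrame(
        {
            "n_input": n_in.astype(int),
            "n_selected": n_sel.astype(int),
            "f_input": f_in,
            "f_selected": f_sel,
            "enrichment": E,
            "log2_enrichment": log2E,
            "zero_input": n_in == 0,
            "zero_selected": n_sel == 0,
        },
        index=pd.Index(peptides, name="peptide"),
    )


def aggregate_replicates(
    tables: List[pd.DataFrame],
    log_scale: bool = False,
) -> pd.DataFrame:
    """Mean and standard deviation of enrichment across replicate tables.

    Averages raw enrichment scores by default (log2 values with
    log_scale=True).  A peptide missing from a replicate is treated as
    missing, not zero; the per-replicate values and mean read counts for
    both samples are carried alongside.  Sample standard deviation (ddof=1)
    is NaN when only one replicate observed the peptide.
    """
    if not tables:
        raise ValueError("need at least one replicate table")
    column = "log2_enrichment" if log_scale else "enrichment"
    e_wide = pd.concat(
        [t[column].rename(f"E_rep{i + 1}") for i, t in enumerate(tables)], axis=1
    )
    in_wide = pd.concat([t["n_input"] for t in tables], axis=1)
    sel_wide = pd.concat([t["n_selected"] for t in tables], axis=1)
    out = pd.DataFrame(
        {
            "mean_E": e_wide.mean(axis=1),
            "sd_E": e_wide.std(axis=1, ddof=1),
            "n_replicates": e_wide.notna().sum(axis=1),
            "mean_n_input": in_wide.mean(axis=1),
            "mean_n_selected": sel_wide.mean(axis=1),
        }
    )
    out = pd.concat([out, e_wide], axis=1)
    out.index.name = "peptide"
    return out
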