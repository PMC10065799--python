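"""Replicate-aware variant-vs-reference effect calling.

For each variant/reference peptide pair the effect is the log2-fold change
of mean enrichment across replicates, tested with a two-sided Welch t-test.
Candidate effects then pass a five-step filter (significance, fold change,
minimum activity, tyrosine-count change, read support), each failure
recorded as a reason code; a pair is a hit iff no code applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .counting import VariantPairList

__all__ = [
    "FilterThresholds",
    "VariantEffect",
    "variant_log2fc",
    "variant_test",
    "tyrosine_change",
    "compute_variant_effects",
    "apply_filters",
    "effects_to_frame",
]

REASON_ORDER = ["not_significant", "small_fold_change", "both_low_activity", "tyr_change", "low_reads"]


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the five-step filter; all configurable.

    alpha: significance level on the variant-vs-reference test.
    min_fold: minimum symmetric fold change, max(FC, 1/FC).
    min_activity: at least one member must have mean enrichment above this,
        so that pairs of two non-substrates are not called.
    min_reads: minimum mean (across replicates) input read count for both
        members, guarding against noise-dominated enrichments.
    """

    alpha: float = 0.05
    min_fold: float = 2.0
    min_activity: float = 1.5
    min_reads: float = 50.0

    def __post_init__(self) -> None:
        for name in ("alpha", "min_fold", "min_activity", "min_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class VariantEffect:
    pair_name: str
    variant: str
    reference: str
    variant_E: List[float]
    reference_E: List[float]
    mean_reads_variant: float
    mean_reads_reference: float
    log2fc: float = math.nan
    p_value: float = math.nan
    tyr_change: bool = False
    verdict: str = "unfiltered"
    reason_codes: List[str] = field(default_factory=list)


def variant_log2fc(variant_E: Sequence[float], reference_E: Sequence[float]) -> float:
    """log2 of the ratio of mean enrichments, variant over reference."""
    if len(variant_E) == 0 or len(reference_E) == 0:
        raise ValueError("need at least one replicate per side")
    mv = float(np.mean(variant_E))
    mr = float(np.mean(reference_E))
    if mv <= 0 or mr <= 0:
        raise ValueError("mean enrichment must be positive to take log2 (apply a pseudocount upstream)")
    return math.log2(mv / mr)


def variant_test(variant_E: Sequence[float], reference_E: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test on replicate enrichments.

    Degenerate zero-variance, zero-difference inputs return p = 1 (no
    evidence of a difference) rather than erroring mid-pipeline.
    """
    if len(variant_E) < 2 or len(reference_E) < 2:
        raise ValueError("Welch test needs >= 2 replicates per side")
    v = np.asarray(variant_E, dtype=float)
    r = np.asarray(reference_E, dtype=float)
    if v.std(ddof=1) == 0 and r.std(ddof=1) == 0:
        return 1.0 if v.mean() == r.mean() else 0.0
    p = stats.ttest_ind(v, r, equal_var=False).pvalue
    if math.isnan(p):
        return 1.0
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def tyrosine_change(variant: str, reference: str) -> bool:
    """True iff the substitution adds or removes a non-central tyrosine.

    Such pairs are ambiguous in a pan-phosphotyrosine readout: a signal
    change can come from the new/lost Tyr being phosphorylated rather than
    from altered recognition of the central site.
    """
    if len(variant) != len(reference):
        raise ValueError("variant and reference must be the same length")
    center = len(variant) // 2
    for name, pep in (("variant", variant), ("reference", reference)):
        if pep[center] != "Y":
            raise ValueError(f"{name} peptide {pep!r} lacks a central tyrosine")
    n_v = variant.count("Y") - 1
    n_r = reference.count("Y") - 1
    return n_v != n_r


def compute_variant_effects(
    replicate_summary: pd.DataFrame,
    pairs: VariantPairList,
    reads_from: str = "input",
) -> List[VariantEffect]:
    """Assemble per-pair effects from a replicate summary (as produced by
    enrichment.aggregate_replicates over the pair universe).

    Uses the per-replicate enrichment columns and the mean read counts of
    each member; read support is taken from the input sample by default
    (library representation), or from the selected sample with
    reads_from="selected".
    """
    if reads_from not in ("input", "selected"):
        raise ValueError("reads_from must be 'input' or 'selected'")
    reads_col = f"mean_n_{reads_from}"
    rep_cols = [c for c in replicate_summary.columns if c.startswith("E_rep")]
    effects = []
    for pair in pairs:
        if pair.variant not in replicate_summary.index or pair.reference not in replicate_summary.index:
            raise KeyError(f"pair {pair.pair_name!r}: member missing from replicate summary")
        v_row = replicate_summary.loc[pair.variant]
        r_row = replicate_summary.loc[pair.reference]
        v_E = [float(v_row[c]) for c in rep_cols if not pd.isna(v_row[c])]
        r_E = [float(r_row[c]) for c in rep_cols if not pd.isna(r_row[c])]
        eff = VariantEffect(
            pair_name=pair.pair_name,
            variant=pair.variant,
            reference=pair.reference,
            variant_E=v_E,
            reference_E=r_E,
            mean_reads_variant=float(v_row[reads_col]),
            mean_reads_reference=float(r_row[reads_col]),
        )
        eff.log2fc = variant_log2fc(v_E, r_E)
        eff.p_value = variant_test(v_E, r_E)
        eff.tyr_change = tyrosine_change(pair.variant, pair.reference)
        effects.append(eff)
    return effects


def apply_filters(
    effects: Iterable[VariantEffect],
    thresholds: FilterThresholds = FilterThresholds(),
    bh_correct: bool = False,
) -> Tuple[List[VariantEffect], List[VariantEffect]]:
    """Annotate every effect with the five-step filter and return
    (all annotated, hits).

    Steps, evaluated in order and all recorded: (1) significance,
    (2) symmetric fold change, (3) minimum activity of at least one member,
    (4) tyrosine-count change, (5) minimum mean read support of both
    members.  A pair is a hit iff no reason code applies.  Raw p-values are
    used by default; bh_correct=True applies a Benjamini-Hochberg adjustment
    before the significance step.
    """
    t = thresholds
    effects = list(effects)
    p_values = [eff.p_value for eff in effects]
    if bh_correct and effects:
        p_values = list(stats.false_discovery_control(p_values, method="bh"))
    annotated: List[VariantEffect] = []
    hits: List[VariantEffect] = []
    for eff, p_eff in zip(effects, p_values):
        codes = []
        if p_eff >= t.alpha:
            codes.append("not_significant")
        fc = 2.0 ** eff.log2fc
        if max(fc, 1.0 / fc) < t.min_fold:
            codes.append("small_fold_change")
        mean_v = float(np.mean(eff.variant_E))
        mean_r = float(np.mean(eff.reference_E))
        if mean_v < t.min_activity and mean_r < t.min_activity:
            codes.append("both_low_activity")
        if eff.tyr_change:
            codes.append("tyr_change")
        if min(eff.mean_reads_variant, eff.mean_reads_reference) < t.min_reads:
            codes.append("low_reads")
        eff.reason_codes = codes
        eff.verdict = "hit" if not codes else "rejected"
        annotated.append(eff)
        if not codes:
            hits.append(eff)
    return annotated, hits


def effects_to_frame(effects: Iterable[VariantEffect]) -> pd.DataFrame:
    """Tabular view mirroring the source-data layout of variant screens."""
    rows = []
    for e in effects:
        rows.append(
            {
                "pair_name": e.pair_name,
                "variant": e.variant,
                "reference": e.reference,
                "mean_E_variant": float(np.mean(e.variant_E)) if e.variant_E else math.nan,
                "sd_E_variant": float(np.std(e.variant_E, ddof=1)) if len(e.variant_E) > 1 else math.nan,
                "mean_E_reference": float(np.mean(e.reference_E)) if e.reference_E else math.nan,
                "sd_E_reference": float(np.std(e.reference_E, ddof=1)) if len(e.reference_E) > 1 else math.nan,
                "mean_reads_variant": e.mean_reads_variant,
                "mean_reads_reference": e.mean_reads_reference,
                "log2fc": e.log2fc,
                "p_value": e.p_value,
                "verdict": e.verdict,
                "reason_codes": ";".join(e.reason_codes),
            }
        )
    return pd.DataFrame(rows)
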