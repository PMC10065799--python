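"""Position-specific count/frequency/log2 matrices."""

import numpy as np
import pandas as pd
import pytest

from pepscreen.pssm import (
    POSITIONS,
    ROW_ORDER,
    PositionMatrix,
    average_matrices,
    position_counts,
    position_enrichment,
    position_frequencies,
    read_matrix_csv,
    write_matrix_csv,
)

from conftest import random_peptides, records_from_peptides


def test_matrix_is_always_21_rows_by_11_columns():
    for mode, peptides in [
        ("nostop", ["AAAAAYAAAAA"]),
        ("full", ["AA*AA*AAAAA"]),
        ("one_amber", ["AA*AAYAAAAA"]),
    ]:
        m = position_counts(records_from_peptides(peptides), mode)
        assert m.values.shape == (21, 11)
        assert list(m.values.index) == ROW_ORDER and m.values.index[20] == "*"
        assert list(m.values.columns) == POSITIONS


def test_single_nostop_peptide_tally():
    m = position_counts(records_from_peptides(["AAAAAYAAAAA"]), "nostop")
    var = [p for p in POSITIONS if p != 0]
    assert (m.values.loc["A", var] == 1).all()
    assert m.values.loc["Y", 0] == 1
    assert m.values.to_numpy().sum() == 11
    assert (m.values.loc["*"] == 0).all()


def test_one_amber_mode_places_single_stop_cell():
    m = position_counts(records_from_peptides(["AA*AAYAAAAA"]), "one_amber")
    star = m.values.loc["*"]
    assert star[-3] == 1 and star.sum() == 1


def test_mode_with_no_qualifying_records_errors_naming_mode():
    with pytest.raises(ValueError, match="nostop"):
        position_counts(records_from_peptides(["AA*AA*AAAAA"]), "nostop")


def test_tally_matches_bruteforce_nested_loop():
    rng = np.random.default_rng(5)
    peptides = random_peptides(rng, 10_000)
    m = position_counts(records_from_peptides(peptides), "nostop")
    oracle = pd.DataFrame(0, index=ROW_ORDER, columns=POSITIONS)
    for pep in peptides:  # naive double loop
        for idx, residue in enumerate(pep):
            oracle.loc[residue, idx - 5] += 1
    assert m.values.equals(oracle)


def test_frequencies_divide_by_column_total():
    peptides = ["AAAAAYAAAAA"] * 3 + ["CCCCCYCCCCC"]
    f = position_frequencies(position_counts(records_from_peptides(peptides), "nostop"))
    assert f.values.loc["A", -5] == 0.75 and f.values.loc["C", -5] == 0.25
    assert np.allclose(f.values.sum(axis=0), 1.0)


def test_random_counts_frequencies_match_arithmetic_oracle():
    rng = np.random.default_rng(6)
    counts = pd.DataFrame(rng.integers(1, 50, size=(21, 11)), index=ROW_ORDER, columns=POSITIONS)
    m = PositionMatrix(counts, layer="counts", mode="full")
    f = position_frequencies(m)
    assert np.allclose(f.values.to_numpy(), counts.to_numpy() / counts.sum(axis=0).to_numpy())


def test_zero_column_total_errors():
    counts = pd.DataFrame(0, index=ROW_ORDER, columns=POSITIONS)
    counts.loc["A", -5] = 1
    with pytest.raises(ValueError, match="zero column total"):
        position_frequencies(PositionMatrix(counts, layer="counts", mode="full"))


def _uniform_freq(mode="full"):
    values = pd.DataFrame(1.0 / 21, index=ROW_ORDER, columns=POSITIONS)
    return PositionMatrix(values, layer="frequency", mode=mode)


def test_equal_frequencies_give_zero_log2():
    log2 = position_enrichment(_uniform_freq(), _uniform_freq(), pseudo_freq=0)
    assert np.allclose(log2.values.to_numpy(), 0.0)


def test_fourfold_frequency_ratio_gives_plus_two():
    sel, inp = _uniform_freq(), _uniform_freq()
    sel.values.loc["A", -5] = 0.4
    inp.values.loc["A", -5] = 0.1
    log2 = position_enrichment(sel, inp, pseudo_freq=0)
    assert log2.values.loc["A", -5] == pytest.approx(2.0)


def test_mode_mismatch_rejected():
    with pytest.raises(ValueError, match="mode mismatch"):
        position_enrichment(_uniform_freq("full"), _uniform_freq("nostop"))


def test_nostop_log2_marks_structural_cells_missing():
    sel = position_frequencies(position_counts(records_from_peptides(["AAAAAYAAAAA"]), "nostop"))
    log2 = position_enrichment(sel, sel)
    assert log2.values.loc["*"].isna().all()
    assert np.isnan(log2.values.loc["A", 0])
    assert log2.values.loc["Y", 0] == 0.0


def test_average_of_identical_matrices_is_identity():
    m = position_enrichment(_uniform_freq(), _uniform_freq(), pseudo_freq=0)
    avg = average_matrices([m, m, m])
    assert np.allclose(avg.values.to_numpy(), m.values.to_numpy())


def test_average_is_cellwise_mean_ignoring_missing():
    base = pd.DataFrame(0.0, index=ROW_ORDER, columns=POSITIONS)
    m1 = PositionMatrix(base + 1.0, layer="log2_enrichment", mode="full")
    m2 = PositionMatrix(base - 1.0, layer="log2_enrichment", mode="full")
    avg = average_matrices([m1, m2])
    assert np.allclose(avg.values.to_numpy(), 0.0)
    withnan = base.copy()
    withnan.loc["A", -5] = np.nan
    m3 = PositionMatrix(withnan + 3.0, layer="log2_enrichment", mode="full")
    avg = average_matrices([m1, m3])
    assert avg.values.loc["A", -5] == 1.0  # only m1 contributes
    rng = np.random.default_rng(9)
    mats = [
        PositionMatrix(pd.DataFrame(rng.normal(size=(21, 11)), index=ROW_ORDER, columns=POSITIONS),
                       layer="log2_enrichment", mode="full")
        for _ in range(3)
    ]
    avg = average_matrices(mats)
    oracle = (mats[0].values + mats[1].values + mats[2].values) / 3
    assert np.allclose(avg.values.to_numpy(), oracle.to_numpy())


def test_matrix_csv_roundtrip(tmp_path):
    m = position_counts(records_from_peptides(["AAAAAYAAAAA", "CCCCCYCCCCC"]), "nostop")
    path = tmp_path / "m.csv"
    write_matrix_csv(m, path)
    back = read_matrix_csv(path)
    assert back.layer == "counts" and back.mode == "nostop"
    assert np.allclose(back.values.to_numpy(dtype=float), m.values.to_numpy(dtype=float))


def test_pooled_counts_sum_replicates():
    from pepscreen.pssm import pool_counts

    m1 = position_counts(records_from_peptides(["AAAAAYAAAAA"]), "nostop")
    m2 = position_counts(records_from_peptides(["CCCCCYCCCCC"] * 2), "nostop")
    pooled = pool_counts([m1, m2])
    assert pooled.values.loc["A", -5] == 1 and pooled.values.loc["C", -5] == 2
    assert pooled.values.to_numpy().sum() == 33


def test_optional_residue_exclusions():
    peptides = ["CAAAAYAAAAA", "AAAAAYAAAAA", "YAAAAYAAAAA"]
    m = position_counts(records_from_peptides(peptides), "nostop", exclude_cys=True)
    assert m.values.loc["C"].sum() == 0 and m.values.to_numpy().sum() == 22
    m = position_counts(records_from_peptides(peptides), "nostop", exclude_noncentral_tyr=True)
    assert m.values.loc["Y", -5] == 0 and m.values.to_numpy().sum() == 22
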