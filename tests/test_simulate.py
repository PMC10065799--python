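"""Synthetic screen generator, NNS statistics and oligo design."""

import re

import numpy as np
import pytest

from pepscreen.pssm import position_counts, position_enrichment, position_frequencies
from pepscreen.seqio import CodingRegion
from pepscreen.simulate import (
    SFII_SITE,
    ScreenTruth,
    amber_codon_fraction,
    design_library_oligos,
    nns_amino_acids,
    nns_codons,
    prob_at_least_one_amber,
    random_truth_matrix,
    reverse_translate,
    sample_nns_library,
    simulate_selection,
    truth_scores,
)
from pepscreen.translation import CODON_TABLE, translate_coding_region

SFII_RE = re.compile(SFII_SITE.replace("N", "[ACGT]"))


def test_nns_codon_enumeration():
    codons = nns_codons()
    assert len(codons) == 32
    assert all(c[2] in "GC" for c in codons)
    assert nns_amino_acids() == set("ACDEFGHIKLMNPQRSTVWY")
    assert amber_codon_fraction() == 1 / 32
    assert "TAA" not in codons or CODON_TABLE["TAA"] != "*"  # TAA unreachable


def test_sampled_library_respects_nns_structure():
    library = sample_nns_library(500, seed=1)
    for dna in library:
        assert len(dna) == 33
        assert dna[15:18] == "TAT"  # fixed central Tyr codon
        for i in range(0, 33, 3):
            if i != 15:
                assert dna[i + 2] in "GC"


def test_amber_containing_fraction_matches_closed_form():
    library = sample_nns_library(100_000, seed=2)
    frac = np.mean([("TAG" in {dna[i:i + 3] for i in range(0, 33, 3)}) for dna in library])
    expected = prob_at_least_one_amber(10)
    se = np.sqrt(expected * (1 - expected) / len(library))
    assert abs(frac - expected) < 3 * se


def test_identical_seeds_give_byte_identical_reads():
    tm = random_truth_matrix(3)
    truth = ScreenTruth(tm, 1.0, 500, 500, seed=4, amber_termination_prob=0.5)
    lib = sample_nns_library(1000, seed=5)
    a_in, a_sel = simulate_selection(lib, truth)
    b_in, b_sel = simulate_selection(lib, truth)
    assert [r.sequence for r in a_in] == [r.sequence for r in b_in]
    assert [r.sequence for r in a_sel] == [r.sequence for r in b_sel]


def test_full_termination_removes_all_stop_peptides_from_selected():
    tm = random_truth_matrix(6)
    truth = ScreenTruth(tm, 1.0, 300, 300, seed=7, amber_termination_prob=1.0)
    lib = sample_nns_library(2000, seed=8)
    _, selected = simulate_selection(lib, truth)
    peptides = [translate_coding_region(CodingRegion("r", r.sequence[36:69])).peptide for r in selected]
    assert all("*" not in p for p in peptides)


def test_truth_scores_match_manual_lookup():
    tm = random_truth_matrix(9)
    pep = "ACDEFYGHIKL"
    expected = np.mean([tm.values.at[pep[i], i - 5] for i in range(11) if i != 5])
    assert truth_scores([pep], tm)[0] == pytest.approx(expected)


def test_favored_residue_recovers_positive_and_top_ranked_cell():
    tm = random_truth_matrix(10, low=0.0, high=0.0)  # flat truth
    tm.values.loc["I", -1] = 2.0  # favor Ile at -1
    truth = ScreenTruth(tm, selection_strength=3.0, depth_input=20_000,
                        depth_selected=20_000, seed=11, amber_termination_prob=0.0)
    lib = sample_nns_library(20_000, seed=12)
    reads_in, reads_sel = simulate_selection(lib, truth)
    def records(reads):
        return [translate_coding_region(CodingRegion(r.read_id, r.sequence[36:69])) for r in reads]
    f_in = position_frequencies(position_counts(records(reads_in), "nostop"))
    f_sel = position_frequencies(position_counts(records(reads_sel), "nostop"))
    log2 = position_enrichment(f_sel, f_in)
    col = log2.values.drop(index="*")[-1]
    assert log2.values.at["I", -1] > 0
    assert col.idxmax() == "I"


def test_selection_strength_zero_keeps_composition_flat():
    tm = random_truth_matrix(13)
    truth = ScreenTruth(tm, selection_strength=0.0, depth_input=20_000,
                        depth_selected=20_000, seed=14, amber_termination_prob=0.0)
    lib = sample_nns_library(20_000, seed=15)
    reads_in, reads_sel = simulate_selection(lib, truth)
    def records(reads):
        return [translate_coding_region(CodingRegion(r.read_id, r.sequence[36:69])) for r in reads]
    f_in = position_frequencies(position_counts(records(reads_in), "nostop"))
    f_sel = position_frequencies(position_counts(records(reads_sel), "nostop"))
    log2 = position_enrichment(f_sel, f_in)
    cells = log2.values.drop(index="*")[[p for p in log2.positions if p != 0]].to_numpy().ravel()
    assert abs(np.mean(cells)) < 3 * np.std(cells) / np.sqrt(len(cells)) + 1e-3


def test_reverse_translation_roundtrip():
    pep = "GGGGGYGGGGG"
    dna = reverse_translate(pep)
    assert "".join(CODON_TABLE[dna[i:i + 3]] for i in range(0, 33, 3)) == pep


def test_oligo_design_preserves_translation_and_reports_gc():
    designs = design_library_oligos(["GGGGGYGGGGG", "ACDEFYGHIKL"])
    for d in designs:
        back = "".join(CODON_TABLE[d.dna[i:i + 3]] for i in range(0, len(d.dna), 3))
        assert back == d.peptide
        assert d.gc_fraction == (d.dna.count("G") + d.dna.count("C")) / len(d.dna)


def test_oligo_design_removes_internal_sfii_sites():
    # naive most-frequent-codon encoding of the GPAGP run contains
    # GGCC CGGCG GGCC, a match to the degenerate SfiI site
    peptide = "AAGPAGPAAAA"
    assert SFII_RE.search(reverse_translate(peptide))
    (design,) = design_library_oligos([peptide])
    assert design.forbidden_site_free
    assert not SFII_RE.search(design.dna)
    back = "".join(CODON_TABLE[design.dna[i:i + 3]] for i in range(0, 33, 3))
    assert back == peptide


def test_oligo_design_raises_gc_of_at_rich_peptides():
    peptide = "F" * 11  # naive encoding TTT x 11 has GC 0
    naive_gc = 0.0
    (design,) = design_library_oligos([peptide])
    assert design.gc_fraction > naive_gc
    assert design.gc_fraction >= 0.30 and design.feasible


def test_infeasible_designs_reported_not_dropped():
    (design,) = design_library_oligos(["F" * 11], gc_bounds=(0.90, 1.00))
    assert not design.feasible and design.note
    back = "".join(CODON_TABLE[design.dna[i:i + 3]] for i in range(0, 33, 3))
    assert back == "F" * 11  # translation still preserved
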