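"""Per-peptide enrichment scores from a defined-library screen.

Builds a tiny defined library, simulates one selection round in which two
peptides are favored, counts reads and computes frequencies (f = n/n_total)
and enrichment scores (E = f_selected / f_input).
"""

from pepscreen import counting, enrichment, pipeline, simulate

peptides = [
    "AAEEIYGEFEA",  # favored: acidic context
    "AADEIYGQFDA",  # favored
    "AAKKIYGKFKA",  # disfavored: basic context
    "AAGGGYGGGGA",
    "AAPPPYPPPPA",
]
library = [simulate.reverse_translate(p) for p in peptides]

truth_matrix = simulate.random_truth_matrix(seed=0, low=0.0, high=0.0)
truth_matrix.values.loc["E", [-3, -2]] = 1.5   # prefer Glu at -3/-2
truth_matrix.values.loc["K", [-3, -2]] = -1.5  # penalize Lys there

truth = simulate.ScreenTruth(truth_matrix, selection_strength=2.0,
                             depth_input=20_000, depth_selected=20_000,
                             seed=4, amber_termination_prob=0.0)
reads_input, reads_selected = simulate.simulate_selection(library, truth)

counts_in = counting.count_peptides(pipeline.reads_to_records(reads_input), sample_id="input")
counts_sel = counting.count_peptides(pipeline.reads_to_records(reads_selected), sample_id="selected")
table = enrichment.enrichment_scores(counts_sel, counts_in, universe=peptides)

print(table[["n_input", "n_selected", "f_input", "f_selected", "enrichment", "log2_enrichment"]].round(4))
print()
print("E > 1: the peptide was captured more often than its input share predicts")
print("(a preferred substrate); E < 1 marks depletion during selection.")
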