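"""Score candidate phosphosites against a recovered specificity matrix.

The raw score of an 11-mer with a central Tyr is the mean log2 enrichment of
its ten variable residues under the matrix; scores are min-max normalized so
the best achievable sequence scores 1 and the worst 0.
"""

from pepscreen import pipeline, scoring, simulate

truth_matrix = simulate.random_truth_matrix(seed=7)
truth = simulate.ScreenTruth(truth_matrix, selection_strength=1.0,
                             depth_input=50_000, depth_selected=50_000,
                             seed=8, amber_termination_prob=0.9)
library = simulate.sample_nns_library(50_000, seed=9)
reads_input, reads_selected = simulate.simulate_selection(library, truth)
matrix = pipeline.run_screen(reads_input, reads_selected, mode="nostop").log2_matrix

consensus = scoring.best_sequence(matrix)
candidates = [consensus, "AAEEIYGEFEA", "AAKKIYGKFKA"]
scores = scoring.score_peptides(candidates, matrix)
print(scores.round(4))
print()
print(f"the consensus {consensus} (per-column argmax) scores exactly 1.0 by construction;")
print("other peptides land between 0 (worst possible) and 1 (best possible substrate).")

delta = scoring.predict_variant_effect("AAEEIYGEFEA", "AAKKIYGKFKA", matrix)
print(f"predicted effect of swapping the basic for the acidic context: {delta:+.4f}")
print("(positive = predicted gain of function on the normalized scale)")
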