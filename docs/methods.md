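# Methods

## Screen deconvolution

The pipeline analyses one round of selection on a surface-displayed peptide
library. Reads are assumed to be already merged paired-end amplicons; the
peptide-coding region is the DNA strictly between two fixed flanks
(5' `ACCGCAGGTACTTCCGTAGCTGGCCAGTCTGGCCAG`,
3' `GGAGGGCAGTCTGGGCAGTCTGGTGACTACAACAAAA`). The six sample-index bases that
border these flanks in the sequencing construct are deliberately excluded
from the match patterns so demultiplexing never affects trimming. Matching
is Hamming-only (no indels) with a per-flank mismatch tolerance,
default 0: exact matching is conservative, reproducible, and — because the
flanks are 36–37 nt — loses only reads with errors inside the flank, which
are uninformative about the insert anyway. The leftmost 5' match is taken,
then the first 3' match after it; reads missing either flank, or with an
empty insert, are discarded with a reason code and an exact discard
fraction is reported per run.

Translation uses the standard genetic code; stops become `*`. The TAG
(Amber) codon is tracked separately from TAA/TGA at the DNA level because
under Amber suppression TAG encodes a non-canonical amino acid: the
`one_amber` counting mode therefore requires the single stop to be
specifically TAG. Reads containing ambiguous bases (N) inside the coding
region are discarded rather than translated to `X`; the counting stages
operate on the exact 20-residue + stop alphabet. The expected peptide
length (11) and central position are parameters, so other library
geometries remain usable.

## Frequencies, enrichment, matrices

Per-sample frequencies are `f = n_peptide / n_total`, with `n_total`
computed over the reads passing the active mode filter — i.e. total reads
are normalized after filtering, which treats each analysis mode as its own
closed universe. Enrichment is `E = f_selected / f_input`. The raw `E`
column is reported without any pseudocount; only the `log2_enrichment`
column adds a pseudocount (default 0.5) to the raw counts of every universe
member in both samples, with frequencies recomputed, so the logarithm is
finite for dropouts. Replicates are aggregated by averaging raw `E`
(log-scale averaging is available behind a flag); the sample standard
deviation uses ddof 1 and is undefined for a single replicate. A peptide
missing from a replicate is missing, not zero.

Position matrices are 21 rows (amino acids in alphabetical one-letter
order, `*` as row 21) by 11 columns (positions −5…+5). Three admission
modes: `nostop` (central Tyr, no stops), `full` (every expected-length
read, used to quantify stop-codon depletion), `one_amber` (central Tyr and
exactly one TAG). Frequencies are column-normalized counts; the log2 layer
is `log2((f_sel + q) / (f_in + q))` with a frequency pseudocount
`q = 1e-4`, small enough to be negligible for observed cells at realistic
depth (expected per-cell frequency ≈ 1/21) while keeping unobserved cells
finite. Cells that are structurally impossible in a mode (the `*` row under
`nostop`; central non-Tyr under `nostop`/`one_amber`) are masked as missing
rather than reported as 0. Replicate matrices are averaged cell-wise on the
log2 layer, ignoring missing cells; pooling counts before the ratio is
available but not the default, since averaging replicate heatmaps weights
each replicate equally regardless of depth. Cys and non-central Tyr rows
are retained by default (an exclusion flag exists) — they carry real
signal, with the caveat that multi-Tyr sequences convolve signal from more
than one acceptor site.

## Scoring

A peptide's raw score is the mean of its residues' log2 enrichments over
the ten variable positions (the fixed central Tyr is ignored). Min-max
normalization maps the best achievable raw score to 1 and the worst to 0;
the extreme scores accumulate per-column maxima/minima in the same
sequential order as peptide scoring so that the argmax/argmin sequences hit
the endpoints exactly, not merely to rounding. Peptides containing `*` are
rejected (a truncated peptide has no display-level meaning); non-central
tyrosines are allowed and scored from the Y row, since natural phosphosite
sequences frequently contain additional tyrosines. Constant matrices cannot
be normalized and raise an error.

## Variant-effect filter

Effects are computed on raw per-replicate enrichment scores: log2 of the
ratio of means, and a two-sided Welch (unequal-variance) t-test. The test
choice is a declared convention — only the significance cutoff is inherent
to the procedure — and is pluggable; no multiple-testing correction is
applied by default (raw p < 0.05), with Benjamini-Hochberg available as an
option. Degenerate zero-variance, zero-difference comparisons return p = 1
(no evidence of a difference). The filter steps run in a fixed order and
every violated step is recorded, so a rejected pair carries all of its
reason codes: `not_significant` (p ≥ α, default 0.05), `small_fold_change`
(max(FC, 1/FC) < 2, symmetric so depletions count like gains),
`both_low_activity` (both mean E < 1.5), `tyr_change` (a non-central Tyr
gained or lost — ambiguous in a pan-phosphotyrosine readout), `low_reads`
(mean input read count of either member < 50). "Read count" is interpreted
as the input-sample count averaged across replicates — input counts measure
library representation independent of the effect being tested; a
selected-count alternative is exposed behind a flag. Hits are pairs with no
codes; the filter is a pure function of (effects, thresholds).

## The simulator

The generator emulates the study conditions of a single-round bead
selection: an NNS-encoded X5-Y-X5 library (five NNS codons, fixed central
TAT, five NNS codons) or a defined library reverse-translated from peptide
lists; input reads drawn uniformly (multinomially) from the library pool;
selected reads drawn with probability proportional to
`exp(strength * score)`, where score is the peptide's mean truth-matrix
value over the variable positions — the simplest Boltzmann-type single-round
selection model. Defaults, chosen once as the simulated study conditions:
depth 1e5 reads per sample (within the 1e4–1e6 range of real runs, deep
enough for stable per-cell estimates at 21 x 11 resolution), selection
strength 1.0, truth log2 entries uniform in [−2, +2], and premature-
termination probability 0.9 for stop-containing members — a stop upstream
of the display scaffold usually, but not always, abolishes display, and the
0.1 complement stands in for read-through/suppression leakage. Every read
is emitted with the full flanks so simulator output exercises the entire
pipeline. All randomness flows from a single seed; identical seeds give
byte-identical read sets.

What the simulator does not model: PCR amplification bias, sequencing
error, bead-capture kinetics, cell-growth effects, and position-coupled
(epistatic) preferences — the truth matrix is strictly additive per
position, as is the PSSM that recovers it. Passing recovery tests therefore
demonstrates that the pipeline inverts its own generative model at
realistic depth, not that real screens are free of those artifacts.

Oligo design reverse-translates with the most frequent E. coli codon per
residue (a fixed usage-ordered table shipped with the package), then swaps
synonymous codons greedily — positions left to right, candidates in
decreasing usage order, accepting only penalty-reducing swaps — until the
GC fraction lies within [0.30, 0.70] and no internal SfiI site
(`GGCCNNNNNGGCC`, scanned on the designed strand) remains. Infeasible
peptides are reported with diagnostics, never dropped; translation is
preserved by construction and re-checked in tests.

## Numerical and interface choices

* Frequencies sum to 1 within 1e-12 per sample; counting is exact integer
  arithmetic.
* Tie-breaks: leftmost flank match; argmax/argmin over matrix columns use
  the first extreme row in row order.
* Matrix CSVs carry a `# layer=... mode=...` header line; counts/paired
  tables are TSV; simulated reads are FASTQ (constant quality `I`) or
  FASTA.
* The CLI is a thin layer over the library; `pipeline` consumes a YAML
  config, removes partial outputs on failure, and writes a manifest with
  parameter values and SHA-256 input checksums. Exit codes: 0 ok,
  2 configuration error, 3 data error.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the simulator at a 1e5-member
library with 1e5 + 1e5 reads for matrix-recovery checks (Pearson r ≥ 0.9
against truth at strength 1.0), 2e4-read samples across 4 replicates for the
null calibration of the variant filter, and 1e4-scale random inputs for the
brute-force oracle comparisons — sizes chosen so every check completes in
seconds while leaving sampling error far below the margins being asserted.

## Known limitations

* PSSMs assume positional independence; inter-residue coupling is out of
  scope.
* No error-correcting collapse of near-identical peptides: each read counts
  once, and sequencing errors appear as distinct low-count species.
* The five-step filter controls the per-pair false-positive rate only
  through the raw p-value cutoff; at thousands of pairs, enabling the
  optional BH correction is advisable.
* Trimming searches the given strand only, as the amplicon protocol fixes
  orientation.
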