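# Methods

## Scoring model

A residue is represented by a k-vector of biochemical property values; the
dissimilarity of an aligned pair is the weighted L1 distance between the
two vectors, with nonnegative weights summing to 1. Gaps incur an affine
penalty g(r) = α + (r − 1)·β with α, β ≥ 0 in the same (distance) units,
and the optimal global alignment minimizes total column distance plus gap
penalties. Terminal gaps are penalized like internal ones (true global
alignment); no local or semi-global mode is provided.

Each property scale is min–max normalized to [0, 1] before alignment
unless normalization is explicitly disabled. Normalization makes scales in
different units commensurable: without it, a scale in cubic ångströms
would dominate one in kcal/mol regardless of the weights. A constant scale
cannot be normalized and is rejected. Consequences of the normalized
weighted-L1 form: every pair distance lies in [0, 1] when normalization is
on, so gap penalties on the (0, 1] grid are directly comparable to
mismatch costs.

## Dynamic programming

The recurrence is the standard three-state affine-gap formulation (match
state plus one insertion state per sequence) rather than a literal scan
over all gap lengths; for affine penalties the two are exactly equivalent,
and the test suite proves the equivalence against brute-force enumeration
of all global alignments of small sequences. A gap in one sequence
immediately followed by a gap in the other is permitted and charged as two
separate gap openings, matching the gap-run reading of the objective.

Determinism: floating-point scores are compared exactly in the DP (all
candidates pass through identical arithmetic), and ties are broken in a
fixed order — diagonal (aligned pair) first, then the gap consuming a
residue of x (vertical), then the gap consuming y. The optimal *score* is
the contract; the specific optimal *path* among co-optimal ones is defined
only by this documented tie-break. The kernel is JIT-compiled with numba
when importable; the pure-Python fallback is the same function and
produces bit-identical results.

The matrix baseline aligner maximizes a conventional substitution-matrix
score with signed gap penalties (e.g. open −16, extend −1, added to the
score). It is implemented by negating the similarities and running the
same minimizing kernel, so both aligners share one traceback convention;
the result records which objective was used, and the two score scales are
never mixed. An independent cross-check against Biopython's
`PairwiseAligner` on random sequence pairs is part of the test suite.

## Residue handling

Input sequences are upper-cased; only the 20 standard amino acids carry
property values. Non-standard letters (B, Z, X, U, O, J) are a hard error
by default, naming the residue and position; an opt-in policy imputes the
per-property mean of the 20 standard values instead. Silent imputation is
not the default because it would change scores invisibly.

## Percent identity and presets

Displayed percent identity uses identical residues over *aligned-pair
columns* (not total alignment columns) by default; both denominators are
available. The preset selector maps an identity estimate to one of five
shipped (weights, α, β) rows covering 0–10, 10–20, 20–30, 30–40 and
above-40 percent identity; intervals are half-open [low, high) so a
boundary value such as 40 falls in the higher range, making selection
deterministic. The 30–40% row is the default parameterization. Identity
auto-estimation aligns with a conventional matrix at open −15 / extend −1;
the documented matrix for this is VTML200 (supplied by the user as a file —
its values are not bundled), with Biopython's BLOSUM62 as the built-in
fallback when no matrix is given. The estimate is a rough pre-alignment
figure and may differ from the final property alignment's identity.

The numeric values of the four bundled default scales (hydrophobicity,
size, coil propensity, thiol group) are implementer-sourced from standard
literature scales — Kyte–Doolittle hydropathy, Zamyatnin residue volumes,
a coil conformational-parameter scale, and a binary cysteine-thiol
indicator — and are fully user-replaceable via the property-file format;
the shipped file's header labels them as sourced. Unit tests that need
concrete numbers use the two-scale example file (hydrophobicity/size with
weights 0.6/0.4), whose values are fixed by the file-format documentation.

## Accuracy metrics

f_D (developer score) is n_I/l_R·100% and f_M (modeler score) is
n_I/l_T·100%, where n_I counts residue-index pairs aligned identically in
test and reference, and l_R/l_T count the reference's/test's aligned
residue pairs; Q is their mean. The "length" quantities are read as
aligned-pair counts, not total alignment columns: under the columns
reading a gapped reference could not score 100 against itself, which
contradicts the metric's role as an accuracy score. The columns reading
remains available behind `length_mode="columns"`. A reference with zero
aligned pairs makes f_D undefined and is an error; a test with zero
aligned pairs scores Q = 0. Q values are ratios of small integers times
100, so exact equality (used to classify head-to-head comparisons as
better/equal/worse by the sign of D = Q1 − Q2) is well defined.

## Grid search

The optimizer is an exhaustive, deterministic scan: every weight vector on
the simplex grid (nonnegative multiples of the step summing to 1;
step 0.05 for the published protocol, giving C(23,3) = 1,771 vectors for
k = 4) crossed with every (α, β) on the gap grid. The full published-scale
search costs n·N^(k+2) alignments — 6,000·20⁶ ≈ 3.8·10¹¹ — which is why
the package's own experiments run coarse grids (e.g. k = 2, step 0.25,
5×5 gap grid) on 20–50 simulated pairs. The gap grid's published step is
0.1 over 10 points; the default range 0.1–1.0 is a package choice
consistent with every shipped preset penalty lying in (0, 1], and is
configurable. Ties in Q_AVER are resolved to the first-encountered grid
point in the documented enumeration order (weights lexicographic, then α,
then β ascending), so results are platform-independent. Per-point
distance tables are constructed exactly as the public aligner constructs
them, making the search's results bit-identical to an external loop over
`align_property`. Families can be capped at 10 pairs (seeded uniform
subsampling without replacement) to limit over-represented families, per
the published protocol. Q_AVER per point is an exact (fsum) mean, so
results are invariant to benchmark ordering.

## Synthetic benchmark

The generator stands in for a structure-based reference-alignment
database: families share a random ancestor (uniform residue frequencies by
default, configurable); each descendant branch applies independent
per-site substitutions (uniform over the other 19 residues) and indel
events (probability split evenly between insertion and deletion, geometric
lengths). The true pairwise alignment is composed from the two branches'
ancestor-coordinate edit histories — ancestor sites deleted on both
branches are dropped, insertions pair with gaps — so references are exact
by construction.

Defaults: 5 families × 4 pairs, ancestor length 100, substitution rate 0.4
per site per branch (two branches agree at an ungapped site with
probability ≈ (1−r)² + r²/19, so r = 0.4 targets ≈ 37% identity — the
default preset's range), indel rate 0.05 per site per branch, mean indel
length 2. Each pair's realized identity assigns it to a preset-range
identity bin. What this does *not* emulate: realistic residue
composition (unless frequencies are supplied), rate heterogeneity across
sites, structural constraints, or real family phylogenies — so passing
tests demonstrate algorithmic correctness and calibration machinery, not
performance on curated structural benchmarks.

## Numerical and I/O choices

Scores are double precision; test tolerances are 1e-9. Weight-sum
validation uses tolerance 1e-9; parsed property files with off-by-more
weights are rejected by default, with an opt-in renormalization policy.
The property-file grammar (header line; canonical 20-letter alphabet line;
`#PROPERTY name` / 20 comma-delimited values / `W:weight` blocks) is
parsed liberally with respect to surrounding whitespace, blank lines and
CRLF endings, and written back so that parse(write(p)) reproduces p
exactly. Substitution matrices are read in BLAST format via Biopython and
must be symmetric. Benchmarks are a directory of two-record aligned-FASTA
references plus a tab-delimited manifest (pair_id, x_id, y_id, reference
path, family_id, identity_bin); everything the package writes is readable
by its own readers.

## Problem sizes used by the shipped experiments

The acceptance script and test suite use: 500 random length-≤6 pairs for
the enumeration-oracle check (exhaustive enumeration is exponential, so
oracle sequences stay tiny); 1,000 random toy alignments for metric
invariants; 30-pair simulated benchmarks (ancestor length 80) for the
method comparison; and 50-pair benchmarks (ancestor length 60) with a
k = 2, 5-point weight, 5×5 gap grid for the optimizer recovery
experiment. These sizes are the package's chosen desk-scale study
conditions; all are parameters, and larger runs only cost time.

## Known limitations

- Exhaustive grid search only; no continuous or gradient-based weight
  optimization.
- No local/semi-global alignment modes; no multiple sequence alignment.
- The minimal-distance objective has no statistical significance theory
  attached here (no e-values); Q comparisons are descriptive.
- Bundled default scale values are literature-derived stand-ins chosen by
  the implementer; analyses that depend on a specific published scale
  should supply it explicitly.
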