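# Methods

## Pairwise identity

Every unique pair of the S input sequences is aligned independently
(S(S−1)/2 alignments) and scored as `1 − M/N`, with `N` the count of
alignment columns where neither row holds a gap and `M` the count of those
columns whose characters differ. Columns with a gap in either row
contribute nothing. `M` and `N` are kept as exact integers throughout;
identity is derived from them and only rounded when formatted (two decimal
places in CSV output), so repeated save/load/extend cycles cannot
accumulate rounding error.

Scoring identity from independent pairwise alignments makes each pair's
value independent of the rest of the dataset — adding or removing other
sequences cannot move it, which is the property the test suite asserts
bit-exactly. The flip side is a known upward bias: even unrelated random
nucleotide sequences average far above the naive 25% expectation once
optimally aligned (the acceptance script measures ≈75–80% under the default
scoring at length 1000), because the aligner gaps out much of the
disagreement and the surviving gap-free columns are enriched for matches.
For classification purposes this bias is conservative: it discourages the
erection of new taxa on marginal divergence.

## Alignment model

The aligner is a strict global Needleman–Wunsch with affine gap costs,
implemented as a three-state Gotoh dynamic programme (match/mismatch,
gap-in-first-row, gap-in-second-row) compiled with numba. A gap of length
L costs `gap_open + gap_extend·(L−1)`. Terminal gaps are penalised like
internal ones; semi-global variants are deliberately out of scope.

Defaults, all overridable per run:

| parameter | nucleotide | amino acid | unit |
|---|---|---|---|
| match / mismatch | +5 / −4 | BLOSUM62 table | score |
| gap_open | 10 | 10 | penalty (first gap column) |
| gap_extend | 0.5 | 0.5 | penalty (each further column) |

The nucleotide values follow the EDNAFULL/EMBOSS-needle convention; no
single historical parameterisation is canonical for this kind of analysis,
so one widely documented convention is fixed and exposed. IUPAC ambiguity
codes are retained verbatim and scored as ordinary characters (identical →
match, different → mismatch); amino-acid characters absent from the
substitution table score +4 when identical and −4 otherwise. These rules
trade biochemical nuance for determinism. `U` is canonicalised to `T` on
nucleotide input so scoring sees one alphabet.

Determinism: traceback ties are resolved diagonal ≻ vertical ≻ horizontal
at every cell, and each pair is ordered lexicographically by id before
alignment, so `align(a,b)` and `align(b,a)` give the same alignment with
rows swapped and every downstream number is bit-reproducible. The same
property makes the result independent of the worker count: pairs are
independent tasks executed on a thread pool (the DP kernel releases the
GIL) and assembled by pair index.

## Alphabet detection

Input is classified as nucleotide when at least 90% of pooled residues are
in `{A,C,G,T,U,N}`, otherwise as amino acid. The 90% figure is an
arbitrary but serviceable cut-off; a CLI flag (`--alphabet nt|aa`)
overrides detection.

## Neighbour-joining leaf order

The matrix is displayed with sequences arranged as the leaves of a rooted
neighbour-joining tree built from `1 − identity` distances (classical
Saitou–Nei Q-minimisation with the standard branch-length formulas;
two-taxon input splits the single distance in half). NJ yields an unrooted
tree and no canonical child order, so conventions are fixed to make the
leaf order reproducible: taxa are canonicalised to lexicographic order
before agglomeration; Q ties join the first eligible pair in that
ordering; the root is placed on the final join, splitting the last edge in
half (which leaves all leaf-to-leaf path lengths unchanged); children are
ladderized by descending subtree size, then by ascending smallest leaf
label. Under these rules an all-tie (all-zero-distance) input degenerates
to plain lexicographic leaf order, and permuting the input rows changes
nothing. Negative branch-length estimates, which arise for non-additive
input, are clamped to zero after estimation; they affect display only.

## Sessions

A finished analysis is saved as a zip archive (`.sdt.zip`) containing
`manifest.json` (format version, alphabet, alignment parameters, SHA-256
checksums), `sequences.fasta` and `pairs.csv` (id_a, id_b, M, N,
identity). The format is deliberately inspectable and diffable; member
timestamps are fixed so identical sessions are byte-identical. Loading
verifies the version and checksums. Extending a session aligns only the
`k·S + k(k−1)/2` pairs that involve new sequences and is exactly
equivalent to a from-scratch run on the union.

## Histograms and figures

The identity-frequency distribution uses 1-percentage-point bins over
[0, 100] by default (configurable; the width must divide 100); bins are
half-open except the last, which includes 100, and each unique pair counts
once. Troughs in this distribution mark identity cut-offs that would
classify with the least ambiguity. Matrix figures paint cells via either a
continuous map scaled to the observed identity range (for contrast) or
discrete colours split at user thresholds; cell values are printed for up
to 30 sequences. SVG/PDF/PNG output embeds no timestamps and uses a fixed
SVG hash salt, so re-rendering is byte-identical.

## Partitioning

Dataset splitting by an inclusive identity range uses single-linkage:
sequences are vertices, in-range pairs are edges, and each connected
component of two or more members becomes one FASTA file (members in input
order), with unlinked sequences collected in `unassigned.fasta`. Single
linkage is the only grouping that guarantees non-overlapping output files;
the price is that transitively linked components may contain pairs outside
the range. A complete-linkage variant guaranteeing all-in-range pairs
would be a natural extension but is not implemented.

## Synthetic families

The fixture generator draws one uniform-random ancestor and derives each
family member independently: substitutions at a per-site fraction
(replacement by one of the three other bases) followed by indels at a
per-site rate with geometric lengths (mean 2, insertions and deletions
equally likely). Two members at divergence *d* therefore sit near
`1 − 2d` identity, slightly higher after back-substitution. This emulates
a star-shaped radiation from a common ancestor — adequate for exercising
identity bands, bimodal family structure and ordering — but not a real
coalescent: it has no shared internal branches, rate variation,
recombination or compositional bias, so passing tests demonstrate the
pipeline's arithmetic and determinism, not classification accuracy on real
genomes. Test and acceptance runs use families of 25–100 sequences of
600–1000 nt at divergences 0.05–0.20 and indel rates 0.002–0.004 — the
shape of small viral-genome datasets at a size a laptop re-runs in
seconds.

## Numerical and degenerate-input choices

* Scores are float64 throughout; DP ties compare exactly, so tie-breaking
  is well defined.
* An alignment with no gap-free column (possible only for pathological
  scoring) raises a "no comparable columns" error rather than returning a
  identity of 0/0.
* Empty files, duplicate ids, residues outside the IUPAC sets, mixed
  alphabets, incomplete pair tables and corrupted session archives all
  raise typed errors naming the offender.
* `gap_extend ≤ gap_open` is enforced; equal values degenerate to linear
  gap costs.

## Known limitations

* No circular-genome rotation normalisation: sequences deposited with
  different origins will align poorly, as with any linear global aligner.
* No local alignment or heuristic acceleration; runtime is O(L²) per pair
  and O(S²) pairs.
* Historical binary session formats from other tools are not readable.
* The NJ rooting/ladderizing conventions are this package's own; other
  software may draw the same tree in a different leaf order.
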