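# demarcate

Pairwise-identity matrices and identity-threshold demarcation for sets of
nucleotide or amino-acid sequences.

Virus taxonomy increasingly relies on genome-wide pairwise identity
thresholds (endorsed by the ICTV for many families) to assign new isolates
to strains, species or genera. Identities computed from a *multiple*
sequence alignment drift as the dataset grows, because the alignment itself
changes; identities computed from *independent pairwise* alignments do not.
`demarcate` takes the pairwise route: it aligns every unique pair of input
sequences with a global (Needleman–Wunsch) affine-gap aligner, scores each
pair, orders the resulting matrix by a neighbour-joining tree, and offers
the displays and dataset operations a classifier needs.

## The statistic

For each of the S(S−1)/2 unique pairs the sequences are globally aligned
and scored as

> identity = 1 − M/N

where **N** is the number of alignment columns in which neither sequence
has a gap character and **M** is the number of those columns whose
characters differ. Columns containing a gap in either row are ignored
entirely, which makes the score insensitive to how indels are penalised at
the margins. Because each pair is aligned independently, a pair's identity
is bit-identical no matter which other sequences are present — the property
that makes identity thresholds stable as datasets grow.

Around the statistic the package provides:

* **seqio** — FASTA reading/writing (plain or gzipped), validation,
  alphabet auto-detection, and a seeded synthetic-family generator for
  testing and demos;
* **pairalign** — an affine-gap Gotoh aligner (match +5 / mismatch −4,
  gap open 10 / extend 0.5 for nucleotides; BLOSUM62 for proteins; all
  overridable) with fixed traceback tie-breaking for bit-reproducibility;
* **identity** — the all-pairs identity matrix, 1 − identity distances,
  long-form and square CSV export, and reloadable/extendable session
  archives (only pairs involving newly added sequences are aligned);
* **treeorder** — an internal neighbour-joining implementation with a
  deterministic rooted leaf order used to arrange the matrix;
* **report** — colour-coded matrix figures (continuous or split at
  demarcation thresholds), identity-frequency histograms whose troughs
  suggest low-conflict cut-offs, PNG/SVG/PDF output;
* **partition** — splitting a dataset into non-overlapping FASTA files by
  an inclusive identity range (single-linkage components).

## Worked example

```sh
demarcate fixtures --out family.fasta --n 6 --length 400 \
    --divergence 0.05 --indel-rate 0.002 --seed 11
demarcate compute --input family.fasta --outdir run --threshold 94
head -4 run/pairs.csv
```

```
id_a,id_b,mismatches,gapfree_columns,identity_pct
seq000,seq001,40,400,90.00
seq000,seq002,44,400,89.00
seq000,seq003,45,400,88.75
```

Each row is one pair: `seq000` and `seq001` disagree at 40 of the 400
gap-free alignment columns, so their identity is 90.00%. Because every
member of this fixture family carries independent substitutions at 5% of
sites, pairwise identities cluster around 1 − 2·0.05 ≈ 90%, as seen.
`run/` also contains `matrix.csv` (the square percent matrix, rows and
columns in neighbour-joining leaf order), `tree.nwk`, the colour-coded
`matrix.svg` split at the 94% threshold, the identity histogram
(`histogram.svg`, `histogram.csv`) and `session.sdt.zip`, which
`demarcate extend` can grow without realigning existing pairs and
`demarcate partition --min 90 --max 100` can split into identity-range
FASTA files.

The same pipeline is available as a library:

```python
from demarcate import read_fasta, all_pairs, neighbor_joining

session = all_pairs(read_fasta("family.fasta"), workers=4)
matrix = session.matrix()
tree = neighbor_joining(matrix.to_distance())
ordered = matrix.reorder(tree.leaf_order)
```

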