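"""Sequence input/output, validation and synthetic test-family generation.

A dataset here is an ordered collection of named sequences sharing one
alphabet (nucleotide or amino acid).  Residues are upper-cased on load and,
for nucleotide data, ``U`` is canonicalised to ``T`` so that downstream
scoring sees a single alphabet.  IUPAC ambiguity codes are accepted and kept
verbatim; they are scored like ordinary characters by the aligner.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino-acid"

# Characters counted as "nucleotide-like" by the alphabet detector.
_NT_CORE = frozenset("ACGTUN")
# Full accepted sets (post U->T canonicalisation for nucleotide data).
NT_ALPHABET = frozenset("ACGTRYSWKMBDHVN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBJZXUO")

#: Fraction of residues that must look nucleotide-like for auto-detection.
DETECT_NT_FRACTION = 0.9

FASTA_WRAP = 70


class SequenceFormatError(ValueError):
    """Raised for malformed or invalid sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence with an alphabet tag.

    Residues are upper-case, contain no gap characters and no whitespace.
    """

    id: str
    residues: str
    alphabet: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceFormatError(f"sequence {self.id!r} is empty")
        if self.alphabet not in (NUCLEOTIDE, AMINO_ACID):
            raise SequenceFormatError(f"unknown alphabet {self.alphabet!r}")
        if "-" in self.residues or any(c.isspace() for c in self.residues):
            raise SequenceFormatError(
                f"sequence {self.id!r} contains gap or whitespace characters"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Dataset:
    """Ordered, duplicate-free collection of records sharing one alphabet."""

    records: list[SequenceRecord]
    alphabet: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SequenceFormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            if rec.alphabet != self.alphabet:
                raise SequenceFormatError(
                    f"record {rec.id!r} has alphabet {rec.alphabet!r}, "
                    f"dataset is {self.alphabet!r}"
                )

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]


def detect_alphabet(residue_strings: Iterable[str]) -> str:
    """Classify raw residue strings as nucleotide or amino acid.

    Returns :data:`NUCLEOTIDE` iff at least 90% of all residues (pooled
    across records) are in ``{A, C, G, T, U, N}``, otherwise
    :data:`AMINO_ACID`.  An explicit alphabet always overrides detection.
    """
    total = 0
    nt_like = 0
    for s in residue_strings:
        s = s.upper()
        total += len(s)
        nt_like += sum(1 for c in s if c in _NT_CORE)
    if total == 0:
        raise SequenceFormatError("no sequences")
    return NUCLEOTIDE if nt_like / total >= DETECT_NT_FRACTION else AMINO_ACID


def _validate_residues(rec_id: str, residues: str, alphabet: str) -> None:
    allowed = NT_ALPHABET if alphabet == NUCLEOTIDE else AA_ALPHABET
    for c in residues:
        if c not in allowed:
            raise SequenceFormatError(
                f"record {rec_id!r}: character {c!r} is not a valid "
                f"{alphabet} residue"
            )


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, alphabet: str = "auto") -> Dataset:
    """Read a (possibly gzipped) multi-record FASTA file into a dataset.

    Records keep file order; residues are upper-cased; the alphabet is
    auto-detected unless ``alphabet`` names one explicitly.  For nucleotide
    data ``U`` is mapped to ``T``.

    Raises :class:`SequenceFormatError` on an empty file, a duplicate id, or
    residues outside the IUPAC nucleotide/amino-acid sets.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        raw = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    if not raw:
        raise SequenceFormatError(f"{path}: no sequences")
    for rec_id, residues in raw:
        if not residues:
            raise SequenceFormatError(f"{path}: record {rec_id!r} is empty")
    if alphabet == "auto":
        alphabet = detect_alphabet(res for _, res in raw)
    elif alphabet not in (NUCLEOTIDE, AMINO_ACID):
        raise SequenceFormatError(f"unknown alphabet {alphabet!r}")

    records = []
    for rec_id, residues in raw:
        if alphabet == NUCLEOTIDE:
            residues = residues.replace("U", "T")
        _validate_residues(rec_id, residues, alphabet)
        records.append(SequenceRecord(rec_id, residues, alphabet))
    return Dataset(records, alphabet)


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> Path:
    """Write records as FASTA, 70-column wrapped, LF line endings.

    Round-trip stable: reading the file back reproduces ids and residues
    exactly.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty record list")
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), FASTA_WRAP):
                fh.write(rec.residues[i : i + FASTA_WRAP] + "\n")
    return path


# ---------------------------------------------------------------------------
# Synthetic families
# ---------------------------------------------------------------------------

_NT_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(rng: np.random.Generator, ancestor: np.ndarray,
            divergence: float, indel_rate: float) -> str:
    """Apply substitutions then geometric-length indels to one ancestor copy."""
    seq = ancestor.copy()
    if divergence > 0:
        hit = rng.random(seq.size) < divergence
        n_hit = int(hit.sum())
        if n_hit:
            # substitute with one of the three other bases
            shift = rng.integers(1, 4, size=n_hit)
            idx = np.searchsorted(
                _NT_CHARS, seq[hit]
            )  # ancestor is drawn from _NT_CHARS, so searchsorted is exact
            seq[hit] = _NT_CHARS[(idx + shift) % 4]
    if indel_rate > 0:
        out: list[np.ndarray] = []
        pos = 0
        events = np.nonzero(rng.random(seq.size) < indel_rate)[0]
        for site in events:
            if site < pos:
                continue
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion before `site`
                out.append(seq[pos:site])
                out.append(_NT_CHARS[rng.integers(0, 4, size=length)])
                pos = site
            else:  # deletion starting at `site`
                out.append(seq[pos:site])
                pos = min(site + length, seq.size)
        out.append(seq[pos:])
        seq = np.concatenate(out) if out else seq
        if seq.size == 0:  # pathological high indel_rate; keep one base
            seq = _NT_CHARS[rng.integers(0, 4, size=1)]
    return seq.tobytes().decode("ascii")


def make_synthetic_family(
    n: int,
    length: int,
    divergence: float,
    indel_rate: float,
    seed: int,
    id_prefix: str = "seq",
    ancestor: str | None = None,
) -> Dataset:
    """Generate a seeded family of related nucleotide sequences.

    One random ancestor of the given length is drawn (or supplied), and each
    of the ``n`` descendants independently receives substitutions at the
    given per-site fraction and insertions/deletions (geometric lengths,
    mean 2) at the given per-site rate.  Deterministic for a fixed seed.

    This emulates a set of sequences radiating from a common ancestor — the
    shape of a within-species genome set — not a full coalescent process.
    """
    if n < 2:
        raise ValueError("a family needs at least 2 sequences")
    if not (0 <= divergence < 1):
        raise ValueError("divergence must be in [0, 1)")
    if not (0 <= indel_rate < 1):
        raise ValueError("indel_rate must be in [0, 1)")
    if length < 1 and ancestor is None:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    if ancestor is None:
        anc = _NT_CHARS[rng.integers(0, 4, size=length)]
    else:
        anc = np.frombuffer(ancestor.upper().encode("ascii"), dtype=np.uint8).copy()
    records = [
        SequenceRecord(f"{id_prefix}{i:03d}",
                       _mutate(rng, anc, divergence, indel_rate),
                       NUCLEOTIDE)
        for i in range(n)
    ]
    return Dataset(records, NUCLEOTIDE)


def random_nucleotide_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform-random nucleotide string (used for null-identity studies)."""
    return _NT_CHARS[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
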