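"""Gap-excluded pairwise identity over all unique sequence pairs.

The central statistic: after globally aligning a pair, identity is
``1 - M/N`` where ``N`` counts alignment columns in which neither row has a
gap and ``M`` counts those gap-free columns whose characters differ.
Columns containing a gap in either row are ignored entirely.  Because every
pair is aligned independently, a pair's identity does not depend on which
other sequences are in the dataset.

Sessions bundle the dataset, the alignment parameters and the complete pair
table so finished analyses can be saved, reloaded and extended without
realigning existing pairs.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pairalign import (AlignParams, PairwiseAlignment, _encode,
                        align_encoded, global_align)
from .seqio import Dataset, SequenceRecord, write_fasta

SESSION_FORMAT_VERSION = "1"
SESSION_EXTENSION = ".sdt.zip"


class IdentityError(ValueError):
    """Raised for invalid identity computations."""


class SessionError(ValueError):
    """Raised for unreadable, corrupted or incompatible session archives."""


def num_pairs(s: int) -> int:
    """Number of unique unordered pairs among ``s`` sequences: s(s-1)/2."""
    if s < 0:
        raise IdentityError("sequence count must be non-negative")
    return s * (s - 1) // 2


@dataclass(frozen=True)
class PairRecord:
    """Identity bookkeeping for one sequence pair.

    ``id_a < id_b`` lexicographically; ``M`` mismatches and ``N`` gap-free
    columns are kept as exact integers, identity is derived as ``1 - M/N``
    and only formatted (e.g. as a percentage) at output time.
    """

    id_a: str
    id_b: str
    M: int
    N: int

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise IdentityError("pair ids must be in strict lexicographic order")
        if not (0 <= self.M <= self.N):
            raise IdentityError("need 0 <= M <= N")
        if self.N < 1:
            raise IdentityError("no comparable columns (N == 0)")

    @property
    def identity(self) -> float:
        return 1.0 - self.M / self.N

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def pair_key(x: str, y: str) -> tuple[str, str]:
    return (x, y) if x < y else (y, x)


def pair_identity(alignment: PairwiseAlignment) -> PairRecord:
    """Count M and N on a finished alignment and build its PairRecord."""
    a = np.frombuffer(alignment.gapped_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(alignment.gapped_b.encode("ascii"), dtype=np.uint8)
    gap = np.uint8(ord("-"))
    gap_free = (a != gap) & (b != gap)
    n = int(gap_free.sum())
    if n == 0:
        raise IdentityError(
            f"pair ({alignment.id_a}, {alignment.id_b}): no comparable columns"
        )
    m = int((a[gap_free] != b[gap_free]).sum())
    ka, kb = pair_key(alignment.id_a, alignment.id_b)
    return PairRecord(ka, kb, m, n)


@dataclass
class DistanceTable:
    """Symmetric pairwise distances (1 - identity), zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise IdentityError("distance table must be square over ids")
        if np.isnan(v).any():
            raise IdentityError("distance table contains NaN")
        if not np.allclose(v, v.T, atol=0.0):
            raise IdentityError("distance table must be symmetric")
        self.values = v


@dataclass
class IdentityMatrix:
    """Symmetric all-pairs identity fractions over S sequences.

    ``ids`` preserve dataset order; the diagonal is exactly 1 and every
    entry lies in [0, 1].
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        s = len(self.ids)
        if v.shape != (s, s):
            raise IdentityError("identity matrix must be square over ids")
        self.values = v
        self._index = {name: i for i, name in enumerate(self.ids)}

    @classmethod
    def from_pairs(cls, ids: Sequence[str],
                   pairs: Iterable[PairRecord]) -> "IdentityMatrix":
        ids = list(ids)
        index = {name: i for i, name in enumerate(ids)}
        values = np.eye(len(ids))
        for p in pairs:
            i, j = index[p.id_a], index[p.id_b]
            values[i, j] = values[j, i] = p.identity
        return cls(ids, values)

    def value(self, id_x: str, id_y: str) -> float:
        return float(self.values[self._index[id_x], self._index[id_y]])

    def to_distance(self) -> DistanceTable:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return DistanceTable(list(self.ids), d)

    def reorder(self, order: Sequence[str]) -> "IdentityMatrix":
        order = list(order)
        if sorted(order) != sorted(self.ids):
            raise IdentityError("order must be a permutation of the matrix ids")
        idx = [self._index[name] for name in order]
        return IdentityMatrix(order, self.values[np.ix_(idx, idx)])

    def write_csv(self, path) -> None:
        """Square-matrix CSV: first row/column are ids, percent values."""
        with open(path, "w", newline="\n") as fh:
            fh.write("," + ",".join(self.ids) + "\n")
            for name, row in zip(self.ids, self.values):
                fh.write(name + "," + ",".join(f"{100 * v:.2f}" for v in row)
                         + "\n")


def to_distance(matrix: IdentityMatrix) -> DistanceTable:
    """Entrywise 1 - identity (the Hamming-style distance used downstream)."""
    return matrix.to_distance()


# ---------------------------------------------------------------------------
# All-pairs computation
# ---------------------------------------------------------------------------

def _compute_pair(a: SequenceRecord, b: SequenceRecord,
                  params: AlignParams) -> PairRecord:
    """Align one canonical pair and reduce it straight to (M, N).

    Equivalent to ``pair_identity(global_align(a, b, params))`` but skips
    materialising the gapped strings; the DP traceback is identical.
    """
    first, second = (a, b) if a.id <= b.id else (b, a)
    ea, eb = _encode(first.residues), _encode(second.residues)
    try:
        _, moves = align_encoded(ea, eb, params)
    except Exception as exc:  # pragma: no cover - defensive
        raise IdentityError(f"pair ({a.id}, {b.id}): {exc}") from exc
    consumes_a = moves != 2
    consumes_b = moves != 1
    ia = np.cumsum(consumes_a) - 1
    ib = np.cumsum(consumes_b) - 1
    diag = moves == 0
    n = int(diag.sum())
    if n == 0:
        raise IdentityError(f"pair ({a.id}, {b.id}): no comparable columns")
    m = int((ea[ia[diag]] != eb[ib[diag]]).sum())
    return PairRecord(first.id, second.id, m, n)


def _compute_pairs(tasks: list[tuple[SequenceRecord, SequenceRecord]],
                   params: AlignParams, workers: int) -> list[PairRecord]:
    if workers <= 1 or len(tasks) < 2:
        return [_compute_pair(a, b, params) for a, b in tasks]
    # Pairs are independent tasks; the DP kernel releases the GIL, so a
    # thread pool parallelises them.  Results are assembled by task index,
    # making output independent of scheduling order.
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(lambda t: _compute_pair(t[0], t[1], params), tasks))


@dataclass
class Session:
    """A finished analysis: dataset + parameters + complete pair table."""

    params: AlignParams
    dataset: Dataset
    pairs: dict[tuple[str, str], PairRecord]
    format_version: str = SESSION_FORMAT_VERSION

    def __post_init__(self) -> None:
        expected = num_pairs(len(self.dataset))
        if len(self.pairs) != expected:
            raise SessionError(
                f"incomplete session: {len(self.pairs)} pairs for "
                f"{len(self.dataset)} sequences (expected {expected})"
            )
        ids = set(self.dataset.ids)
        for ka, kb in self.pairs:
            if ka not in ids or kb not in ids:
                raise SessionError(f"pair ({ka}, {kb}) references unknown ids")

    @property
    def sorted_pairs(self) -> list[PairRecord]:
        return [self.pairs[k] for k in sorted(self.pairs)]

    def matrix(self) -> IdentityMatrix:
        return IdentityMatrix.from_pairs(self.dataset.ids, self.pairs.values())


def all_pairs(dataset: Dataset, params: AlignParams | None = None,
              workers: int = 1) -> Session:
    """Align every unique pair (S sequences -> S(S-1)/2 alignments).

    The result is bit-identical for any worker count.
    """
    if len(dataset) < 2:
        raise IdentityError("all-pairs computation needs at least 2 sequences")
    if params is None:
        params = AlignParams.for_alphabet(dataset.alphabet)
    recs = dataset.records
    tasks = [(recs[i], recs[j])
             for i in range(len(recs)) for j in range(i + 1, len(recs))]
    pair_list = _compute_pairs(tasks, params, workers)
    return Session(params, dataset, {p.key: p for p in pair_list})


def extend_session(session: Session, new_records: Sequence[SequenceRecord],
                   workers: int = 1) -> Session:
    """Add sequences, aligning only pairs that involve a new sequence.

    For k additions to S existing sequences exactly ``k*S + k(k-1)/2`` new
    alignments are computed; the result equals a from-scratch run on the
    union, pair for pair.
    """
    new_records = list(new_records)
    existing = set(session.dataset.ids)
    for rec in new_records:
        if rec.id in existing:
            raise SessionError(f"id {rec.id!r} already present in session")
        if rec.alphabet != session.dataset.alphabet:
            raise SessionError(
                f"record {rec.id!r} alphabet {rec.alphabet!r} does not match "
                f"session alphabet {session.dataset.alphabet!r}"
            )
        existing.add(rec.id)
    tasks = [(old, new) for new in new_records for old in session.dataset.records]
    tasks += [(new_records[i], new_records[j])
              for i in range(len(new_records))
              for j in range(i + 1, len(new_records))]
    new_pairs = _compute_pairs(tasks, session.params, workers)
    merged = dict(session.pairs)
    merged.update({p.key: p for p in new_pairs})
    dataset = Dataset(session.dataset.records + new_records,
                      session.dataset.alphabet)
    return Session(session.params, dataset, merged)


# ---------------------------------------------------------------------------
# CSV export and session archives
# ---------------------------------------------------------------------------

PAIRS_CSV_HEADER = "id_a,id_b,mismatches,gapfree_columns,identity_pct"


def format_pairs_csv(pairs: Iterable[PairRecord]) -> str:
    """Long-form CSV, pairs sorted lexicographically, identity% to 2 dp."""
    lines = [PAIRS_CSV_HEADER]
    for p in sorted(pairs, key=lambda p: p.key):
        lines.append(f"{p.id_a},{p.id_b},{p.M},{p.N},{100 * p.identity:.2f}")
    return "\n".join(lines) + "\n"


def write_pairs_csv(pairs: Iterable[PairRecord], path) -> None:
    Path(path).write_text(format_pairs_csv(pairs))


def _session_pairs_table(session: Session) -> str:
    lines = ["id_a,id_b,M,N,identity"]
    for p in session.sorted_pairs:
        lines.append(f"{p.id_a},{p.id_b},{p.M},{p.N},{p.identity!r}")
    return "\n".join(lines) + "\n"


def save_session(session: Session, path) -> Path:
    """Write a session archive: a zip of manifest.json + FASTA + pair table.

    The manifest records the format version, alignment parameters, alphabet
    and SHA-256 checksums of the payload members, so corruption is detected
    on load.  Archive bytes are deterministic (fixed member timestamps).
    """
    path = Path(path)
    # reuse the canonical FASTA writer via a temp file
    import tempfile

    with tempfile.NamedTemporaryFile("r", suffix=".fasta") as tmp:
        write_fasta(session.dataset.records, tmp.name)
        fasta_text = Path(tmp.name).read_text()
    pairs_text = _session_pairs_table(session)
    manifest = {
        "format_version": session.format_version,
        "alphabet": session.dataset.alphabet,
        "params": session.params.to_dict(),
        "n_sequences": len(session.dataset),
        "sha256": {
            "sequences.fasta": hashlib.sha256(fasta_text.encode()).hexdigest(),
            "pairs.csv": hashlib.sha256(pairs_text.encode()).hexdigest(),
        },
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, text in (
            ("manifest.json", json.dumps(manifest, indent=1, sort_keys=True)),
            ("sequences.fasta", fasta_text),
            ("pairs.csv", pairs_text),
        ):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, text)
    return path


def load_session(path) -> Session:
    """Reload a saved session archive, verifying version and checksums."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            fasta_text = zf.read("sequences.fasta").decode()
            pairs_text = zf.read("pairs.csv").decode()
    except (zipfile.BadZipFile, KeyError, OSError) as exc:
        raise SessionError(f"{path}: corrupted or unreadable session archive "
                           f"({exc})") from exc
    if manifest.get("format_version") != SESSION_FORMAT_VERSION:
        raise SessionError(
            f"{path}: unsupported session format version "
            f"{manifest.get('format_version')!r}"
        )
    for name, text in (("sequences.fasta", fasta_text), ("pairs.csv", pairs_text)):
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != manifest["sha256"][name]:
            raise SessionError(f"{path}: checksum mismatch for {name}")

    import tempfile

    from .seqio import read_fasta

    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as tmp:
        tmp.write(fasta_text)
        tmp_path = tmp.name
    try:
        dataset = read_fasta(tmp_path, alphabet=manifest["alphabet"])
    finally:
        Path(tmp_path).unlink(missing_ok=True)

    pairs: dict[tuple[str, str], PairRecord] = {}
    lines = pairs_text.strip().split("\n")
    for line in lines[1:]:
        id_a, id_b, m, n, _identity = line.split(",")
        rec = PairRecord(id_a, id_b, int(m), int(n))
        pairs[rec.key] = rec
    params = AlignParams.from_dict(manifest["params"])
    return Session(params, dataset, pairs,
                   format_version=manifest["format_version"])
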