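"""Split a dataset into non-overlapping FASTA files by an identity range.

Sequences are grouped by single linkage: build a graph with an edge for
every pair whose percent identity lies inside the (inclusive) requested
range, and emit each connected component with at least two members as one
FASTA file.  Sequences with no in-range partner go to ``unassigned.fasta``.
Because linkage is transitive, a component can contain pairs outside the
range; complete-linkage grouping would avoid that but could not produce
non-overlapping files, so it is left as an extension point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .identity import IdentityError, PairRecord, num_pairs
from .seqio import Dataset, write_fasta

UNASSIGNED_NAME = "unassigned.fasta"
MANIFEST_NAME = "partition_manifest.csv"


@dataclass(frozen=True)
class PartitionSpec:
    """Inclusive percent-identity bounds selecting the in-range pairs."""

    min_identity: float
    max_identity: float

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity <= self.max_identity <= 100):
            raise ValueError("need 0 <= min <= max <= 100")

    def contains(self, identity_fraction: float) -> bool:
        pct = 100.0 * identity_fraction
        return self.min_identity <= pct <= self.max_identity


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


@dataclass
class PartitionResult:
    """Mapping of component files to member ids, plus the unassigned set."""

    files: list[Path]
    membership: dict[str, str]  # id -> file name
    components: list[list[str]]
    unassigned: list[str]


def group_by_identity(dataset: Dataset,
                      pairs: Mapping[tuple[str, str], PairRecord] | Iterable[PairRecord],
                      spec: PartitionSpec) -> tuple[list[list[str]], list[str]]:
    """Single-linkage components of the in-range identity graph.

    Returns (components with >= 2 members, unassigned ids); members keep
    dataset input order, components are ordered by their first member.
    """
    if len(dataset) == 0:
        raise IdentityError("empty dataset")
    pair_list = list(pairs.values()) if isinstance(pairs, Mapping) else list(pairs)
    ids = dataset.ids
    known = set(ids)
    for p in pair_list:
        if p.id_a not in known or p.id_b not in known:
            raise IdentityError(f"pair ({p.id_a}, {p.id_b}) references unknown ids")
    if len(pair_list) != num_pairs(len(dataset)):
        raise IdentityError(
            f"incomplete pair set: {len(pair_list)} pairs for {len(dataset)} "
            f"sequences (expected {num_pairs(len(dataset))})"
        )
    uf = _UnionFind(ids)
    linked: set[str] = set()
    for p in pair_list:
        if spec.contains(p.identity):
            uf.union(p.id_a, p.id_b)
            linked.add(p.id_a)
            linked.add(p.id_b)
    groups: dict[str, list[str]] = {}
    for name in ids:  # input order
        groups.setdefault(uf.find(name), []).append(name)
    components = [g for g in groups.values() if len(g) >= 2]
    unassigned = [name for name in ids if name not in linked]
    return components, unassigned


def partition_by_identity(dataset: Dataset,
                          pairs,
                          spec: PartitionSpec,
                          out_dir) -> PartitionResult:
    """Write one FASTA per component plus unassigned.fasta and a manifest.

    Output files are pairwise disjoint and their union is the dataset; the
    manifest CSV maps every sequence id to the file that holds it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    components, unassigned = group_by_identity(dataset, pairs, spec)
    files: list[Path] = []
    membership: dict[str, str] = {}
    for k, comp in enumerate(components, start=1):
        name = f"partition_{k:03d}.fasta"
        write_fasta([dataset[i] for i in comp], out_dir / name)
        files.append(out_dir / name)
        for member in comp:
            membership[member] = name
    if unassigned:
        write_fasta([dataset[i] for i in unassigned], out_dir / UNASSIGNED_NAME)
        files.append(out_dir / UNASSIGNED_NAME)
        for member in unassigned:
            membership[member] = UNASSIGNED_NAME
    manifest = out_dir / MANIFEST_NAME
    with open(manifest, "w", newline="\n") as fh:
        fh.write("id,file\n")
        for name in dataset.ids:
            fh.write(f"{name},{membership[name]}\n")
    return PartitionResult(files, membership, components, unassigned)
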