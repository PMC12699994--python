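"""Sequence and tree I/O.

Reads per-locus FASTA files (one sequence per individual; plain or gzipped),
merges individuals into populations by label prefix, chunks raw reads into
pseudo-loci, and round-trips Newick trees with branch lengths and support
labels via dendropy.

The on-disk layout for a multilocus dataset is one FASTA file per locus in a
directory; lexicographic file order defines locus order.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "LocusData",
    "DatasetBundle",
    "read_locus_fasta",
    "write_locus_fasta",
    "read_dataset",
    "merge_by_prefix",
    "concatenate_reads",
    "read_newick",
    "write_newick",
    "trees_to_newick",
]

_FASTA_SUFFIXES = (".fasta", ".fa", ".fna", ".fasta.gz", ".fa.gz", ".fna.gz")


@dataclass
class LocusData:
    """One locus: an ordered mapping of group/individual label -> DNA string.

    ``aligned=True`` asserts that all sequences have equal length (gaps
    included); tokenization modes that operate on alignment columns require
    it.
    """

    locus_id: str
    documents: dict[str, str]
    aligned: bool = False

    def __post_init__(self) -> None:
        if len(self.documents) < 2:
            raise ValueError(
                f"locus {self.locus_id!r} needs at least 2 sequences, "
                f"got {len(self.documents)}"
            )
        for label, seq in self.documents.items():
            if not seq:
                raise ValueError(f"locus {self.locus_id!r}: empty sequence for {label!r}")
        if self.aligned:
            lengths = {len(s) for s in self.documents.values()}
            if len(lengths) > 1:
                raise ValueError(
                    f"locus {self.locus_id!r} marked aligned but sequence "
                    f"lengths differ: {sorted(lengths)}"
                )

    @property
    def labels(self) -> list[str]:
        return list(self.documents)

    def alignment_length(self) -> int:
        if not self.aligned:
            raise ValueError(f"locus {self.locus_id!r} is not aligned")
        return len(next(iter(self.documents.values())))


@dataclass
class DatasetBundle:
    """An ordered collection of loci sharing a canonical tip ordering."""

    loci: list[LocusData]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group_order and self.loci:
            self.group_order = self.loci[0].labels
        order = set(self.group_order)
        for locus in self.loci:
            extra = [lab for lab in locus.labels if lab not in order]
            if extra:
                raise ValueError(
                    f"locus {locus.locus_id!r} has labels outside group_order: {extra}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_locus_fasta(path: str | Path, aligned: bool = False) -> LocusData:
    """Parse one locus FASTA file (plain or .gz) into a :class:`LocusData`.

    The label is the header token up to the first whitespace; sequences are
    uppercased. Duplicate labels, empty sequences, and (for ``aligned=True``)
    unequal lengths raise ``ValueError``.
    """
    path = Path(path)
    locus_id = path.name
    for suf in _FASTA_SUFFIXES:
        if locus_id.endswith(suf):
            locus_id = locus_id[: -len(suf)]
            break
    documents: dict[str, str] = {}
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            label = record.id
            if label in documents:
                raise ValueError(f"duplicate label {label!r} in {path}")
            documents[label] = str(record.seq).upper()
    if len(documents) < 2:
        raise ValueError(f"{path}: expected at least 2 FASTA records, got {len(documents)}")
    return LocusData(locus_id=locus_id, documents=documents, aligned=aligned)


def write_locus_fasta(locus: LocusData, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for label, seq in locus.documents.items():
            fh.write(f">{label}\n{seq}\n")


def read_dataset(
    directory: str | Path,
    aligned: bool = False,
    merging: int | None = None,
) -> DatasetBundle:
    """Read every FASTA file in *directory* (lexicographic order) as loci.

    If *merging* is given, individuals whose labels share the same first
    ``merging`` characters are pooled into one document per group
    (:func:`merge_by_prefix`).
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.name.endswith(_FASTA_SUFFIXES)
    )
    if not paths:
        raise FileNotFoundError(f"no FASTA files in {directory}")
    loci = [read_locus_fasta(p, aligned=aligned) for p in paths]
    if merging is not None:
        loci = [merge_by_prefix(locus, merging) for locus in loci]
    group_order: list[str] = []
    seen = set()
    for locus in loci:
        for lab in locus.labels:
            if lab not in seen:
                seen.add(lab)
                group_order.append(lab)
    return DatasetBundle(loci=loci, group_order=group_order)


def merge_by_prefix(locus: LocusData, n: int) -> LocusData:
    """Pool individuals whose labels share the same first *n* characters.

    Sequences of a group are concatenated in input order, so the group's
    k-mer multiset is the union of its members' (bag-of-words pooling).
    Merging an aligned locus yields an unaligned one unless group sizes are
    equal; the flag is recomputed from the result.
    """
    if n < 1:
        raise ValueError("prefix length n must be >= 1")
    if all(len(label) < n for label in locus.documents):
        raise ValueError(
            f"prefix length {n} exceeds every label length in locus {locus.locus_id!r}"
        )
    merged: dict[str, str] = {}
    for label, seq in locus.documents.items():
        prefix = label[:n]
        merged[prefix] = merged.get(prefix, "") + seq
    lengths = {len(s) for s in merged.values()}
    still_aligned = locus.aligned and len(lengths) == 1
    return LocusData(locus_id=locus.locus_id, documents=merged, aligned=still_aligned)


def concatenate_reads(reads: Sequence[str], chunk: int) -> list[str]:
    """Concatenate every *chunk* consecutive reads into one pseudo-locus
    sequence (final partial chunk kept). Used to turn raw long-read FASTA
    into a manageable number of long documents."""
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    if not reads:
        raise ValueError("empty read list")
    return ["".join(reads[i : i + chunk]) for i in range(0, len(reads), chunk)]


# -- Newick ----------------------------------------------------------------


def read_newick(path: str | Path, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Read a Newick tree; internal node labels are kept as supports."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write(tree_to_newick_string(tree) + "\n")


def tree_to_newick_string(tree: dendropy.Tree) -> str:
    """Canonical Newick with branch lengths at 10 significant digits."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()


def trees_to_newick(trees: Iterable[dendropy.Tree], path: str | Path) -> None:
    """Write a multi-tree Newick file, one tree per line (bootstrap sets)."""
    with open(path, "wt") as fh:
        for tree in trees:
            fh.write(tree_to_newick_string(tree) + "\n")
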