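"""Alignment and tree I/O, gap statistics, and patristic distance matrices.

A *family* is a labelled multiple sequence alignment (MSA) of homologous
proteins together with one or more phylogenetic trees inferred for it.  The
central derived object is the patristic distance matrix: for every pair of
leaves, the sum of branch lengths along the unique path connecting them.
When several replicate trees are available (e.g. inferred under different
random seeds), their patristic matrices are averaged element-wise into a
single reference matrix against which representation spaces are compared.

Gap statistics classify a family into a low-gap (<= 20% gap characters) or
high-gap (>= 70%) regime, provided it has at least 200 sequences of aligned
length >= 70; these regimes behave very differently for alignment-aware
models and are kept separate throughout the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHAR = "-"
#: Ambiguity / non-standard codes folded into 'X' (B=Asx, Z=Glx, U=Sec, O=Pyl).
AMBIGUOUS_RESIDUES = {"B": "X", "Z": "X", "U": "X", "O": "X", "X": "X"}
#: Working alphabet: the 20 canonical residues plus the ambiguity symbol.
WORKING_ALPHABET = AMINO_ACIDS + "X"

LOW_GAP_MAX = 0.20
HIGH_GAP_MIN = 0.70
MIN_SEQUENCES = 200
MIN_LENGTH = 70

DISTANCE_KINDS = ("patristic", "embedding", "onehot", "attention_similarity")


class AlignmentFormatError(ValueError):
    """Raised for ragged rows or an unparseable alignment file."""


class LabelError(ValueError):
    """Raised for duplicate, missing, or mismatched sequence labels."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside the alphabet."""


class EmptySequenceError(ValueError):
    """Raised when gap removal leaves a sequence with no residues."""


class TreeFormatError(ValueError):
    """Raised for malformed Newick input."""


class LeafSetMismatchError(ValueError):
    """Raised when replicate trees do not share a leaf label set."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedFamily:
    """A labelled MSA over the amino-acid alphabet plus the gap symbol."""

    family_id: str
    labels: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: str = WORKING_ALPHABET
    gap_char: str = GAP_CHAR

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise LabelError("labels and rows must be equinumerous")
        if len(set(self.labels)) != len(self.labels):
            dupes = {l for l in self.labels if self.labels.count(l) > 1}
            raise LabelError(f"duplicate sequence labels: {sorted(dupes)}")
        if not self.rows:
            raise AlignmentFormatError("alignment has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"ragged alignment: row lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentFormatError("alignment length must be >= 1")
        allowed = set(self.alphabet) | {self.gap_char}
        for label, row in zip(self.labels, self.rows):
            bad = set(row) - allowed
            if bad:
                raise AlphabetError(
                    f"row {label!r} contains characters outside the alphabet: "
                    f"{sorted(bad)}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class SequenceSet:
    """Unaligned (gap-free) labelled protein sequences."""

    labels: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise LabelError("labels and sequences must be equinumerous")
        if len(set(self.labels)) != len(self.labels):
            raise LabelError("duplicate sequence labels")
        for label, seq in zip(self.labels, self.sequences):
            if GAP_CHAR in seq:
                raise AlphabetError(f"sequence {label!r} contains gap characters")
            if not seq:
                raise EmptySequenceError(f"sequence {label!r} is empty")


@dataclass
class PhyloTree:
    """A phylogenetic tree with branch lengths, backed by dendropy.

    Patristic distance is invariant to rooting, so no distinction between
    rooted and unrooted input is made anywhere downstream.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise LabelError("duplicate leaf labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is None:
                continue
            if not math.isfinite(edge.length) or edge.length < 0:
                raise TreeFormatError(
                    f"branch length {edge.length!r} is not finite and >= 0"
                )

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeFormatError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


@dataclass
class DistanceMatrix:
    """A symmetric labelled matrix of pairwise distances or similarities.

    ``kind`` records provenance: patristic (tree), embedding (Euclidean in a
    representation space), onehot (Euclidean between composition vectors), or
    attention_similarity (symmetrized column attention; the only kind allowed
    a nonzero diagonal and negative entries).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in DISTANCE_KINDS:
            raise ValueError(f"unknown distance-matrix kind {self.kind!r}")
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise LabelError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-8, rtol=0.0):
            raise ValueError("distance matrix is not symmetric")
        if self.kind != "attention_similarity":
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
                raise ValueError(f"{self.kind} matrix must have a zero diagonal")
            if np.any(self.values < 0):
                raise ValueError(f"{self.kind} matrix must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise LabelError(f"label {label!r} not in matrix") from None

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns permuted to ``labels`` order."""
        if set(labels) != set(self.labels):
            raise LabelError("label sets differ; cannot reorder")
        idx = np.array([self.labels.index(l) for l in labels])
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.kind)

    def condensed(self) -> np.ndarray:
        """Strict upper triangle, row-major — the information-bearing entries."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", index_label="label")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise LabelError("row and column labels differ in matrix TSV")
        return cls(tuple(str(l) for l in df.index), df.to_numpy(float), kind)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _clean_row(label: str, row: str) -> str:
    """Uppercase, map Stockholm '.' to '-', and fold ambiguity codes to X."""
    out = []
    for ch in row.upper():
        if ch == ".":
            ch = GAP_CHAR
        ch = AMBIGUOUS_RESIDUES.get(ch, ch)
        if ch != GAP_CHAR and ch not in WORKING_ALPHABET:
            raise AlphabetError(
                f"row {label!r} contains unknown character {ch!r}"
            )
        out.append(ch)
    return "".join(out)


def read_alignment(
    path: str | Path, format: str = "fasta", family_id: str | None = None
) -> AlignedFamily:
    """Read an MSA from FASTA or Stockholm, preserving file row order.

    Residues are uppercased, Stockholm '.' gaps mapped to '-', and ambiguity
    codes (B, Z, U, O) folded into 'X'.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        msg = str(exc).lower()
        if "duplicate" in msg:
            raise LabelError(str(exc)) from exc
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    labels = tuple(rec.id for rec in msa)
    if len(set(labels)) != len(labels):
        raise LabelError(f"duplicate sequence labels in {path}")
    rows = tuple(_clean_row(rec.id, str(rec.seq)) for rec in msa)
    return AlignedFamily(
        family_id=family_id or Path(path).stem, labels=labels, rows=rows
    )


def write_alignment(fam: AlignedFamily, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment as FASTA or Stockholm."""
    records = [
        SeqRecord(Seq(row), id=label, description="")
        for label, row in zip(fam.labels, fam.rows)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), format)


def gap_percentage(fam: AlignedFamily) -> float:
    """Gap characters divided by total characters (N x L) in the MSA."""
    total = fam.n_sequences * fam.length
    gaps = sum(row.count(fam.gap_char) for row in fam.rows)
    return gaps / total


def classify_gap_category(fam: AlignedFamily, enforce_size: bool = True) -> str:
    """Classify a family as 'low_gap', 'high_gap', or 'neither'.

    Low-gap requires gap fraction <= 0.20, high-gap >= 0.70; both additionally
    require N >= 200 sequences of aligned length >= 70 unless ``enforce_size``
    is disabled (useful for toy data).
    """
    gap = gap_percentage(fam)
    size_ok = (not enforce_size) or (
        fam.n_sequences >= MIN_SEQUENCES and fam.length >= MIN_LENGTH
    )
    if size_ok and gap <= LOW_GAP_MAX:
        return "low_gap"
    if size_ok and gap >= HIGH_GAP_MIN:
        return "high_gap"
    return "neither"


def degap(fam: AlignedFamily) -> SequenceSet:
    """Delete gap characters from every row, preserving label order."""
    seqs = []
    for label, row in zip(fam.labels, fam.rows):
        seq = row.replace(fam.gap_char, "")
        if not seq:
            raise EmptySequenceError(f"row {label!r} is entirely gaps")
        seqs.append(seq)
    return SequenceSet(labels=fam.labels, sequences=tuple(seqs))


def read_trees(paths: Iterable[str | Path]) -> list[PhyloTree]:
    """Read replicate Newick trees; all must share one leaf label set."""
    paths = list(paths)
    trees = []
    for path in paths:
        try:
            tree = dendropy.Tree.get(
                path=str(path), schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise TreeFormatError(f"{path}: malformed Newick ({exc})") from exc
        trees.append(PhyloTree(tree))
    if trees:
        ref = set(trees[0].leaf_labels)
        for path, t in zip(list(paths)[1:], trees[1:]):
            if set(t.leaf_labels) != ref:
                raise LeafSetMismatchError(
                    f"{path}: leaf set differs from first replicate"
                )
    return trees


def patristic_matrix(
    tree: PhyloTree, label_order: Sequence[str] | None = None
) -> DistanceMatrix:
    """All-pairs patristic distances (path sums of branch lengths).

    Each pair's path is found through parent pointers up to the most recent
    common ancestor and its branch lengths accumulated with ``math.fsum``,
    so results do not depend on summation order.
    """
    leaves = {leaf.taxon.label: leaf for leaf in tree.tree.leaf_node_iter()}
    if label_order is None:
        label_order = tuple(leaves)
    missing = set(label_order) - set(leaves)
    if missing:
        raise LabelError(f"labels not in tree: {sorted(missing)}")

    # Path from each leaf to the root as (node, cumulative edge list).
    def path_to_root(node):
        edges = []
        nodes = []
        while node is not None:
            nodes.append(node)
            if node.edge is not None and node.edge.length is not None:
                edges.append(node.edge.length)
            else:
                edges.append(0.0)
            node = node.parent_node
        return nodes, edges

    paths = {label: path_to_root(leaves[label]) for label in label_order}
    n = len(label_order)
    values = np.zeros((n, n))
    for i in range(n):
        nodes_i, edges_i = paths[label_order[i]]
        depth_i = {id(nd): k for k, nd in enumerate(nodes_i)}
        for j in range(i + 1, n):
            nodes_j, edges_j = paths[label_order[j]]
            for kj, nd in enumerate(nodes_j):
                ki = depth_i.get(id(nd))
                if ki is not None:
                    break
            else:  # pragma: no cover - disconnected tree cannot parse
                raise TreeFormatError("leaves share no common ancestor")
            d = math.fsum(edges_i[:ki] + edges_j[:kj])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(label_order), values, "patristic")


def average_matrices(mats: Sequence[DistanceMatrix]) -> DistanceMatrix:
    """Element-wise mean of replicate matrices after label reordering."""
    if not mats:
        raise ValueError("cannot average an empty list of matrices")
    kinds = {m.kind for m in mats}
    if len(kinds) != 1:
        raise ValueError(f"cannot average matrices of mixed kinds {kinds}")
    ref = mats[0]
    aligned = [m.reorder(ref.labels).values for m in mats]
    return DistanceMatrix(ref.labels, np.mean(aligned, axis=0), ref.kind)
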