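"""Comparison spaces: pooled embeddings, composition vectors, column attention.

Three spaces are compared against the patristic reference matrix:

* an embedding space — one D-dimensional vector per sequence, typically the
  mean over per-residue vectors of a protein language model layer;
* a composition ("onehot") space — the relative amino-acid frequency vector
  of each sequence, insensitive to residue order;
* a column-attention space — an N x N attention matrix between sequences,
  made symmetric by adding its transpose.

Distances within the first two are Euclidean.  Neuron masking restricts an
embedding space to a column subset, the primitive behind saliency ablation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .family_io import (
    AlignedFamily,
    DistanceMatrix,
    EmptySequenceError,
    LabelError,
    SequenceSet,
    WORKING_ALPHABET,
)


@dataclass(frozen=True)
class NeuronSet:
    """A subset of neuron (column) indices of an embedding space, 0-based."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(set(int(i) for i in self.indices)))
        object.__setattr__(self, "indices", idx)
        if any(i < 0 for i in idx):
            raise IndexError("neuron indices must be nonnegative")

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)

    def intersection(self, other: "NeuronSet") -> "NeuronSet":
        return NeuronSet(tuple(set(self.indices) & set(other.indices)))


@dataclass
class RepresentationSet:
    """An N x D matrix of per-sequence vectors for one (model, layer)."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    model_tag: str = "model"
    layer_tag: str = "output"

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("representation matrix must be 2-dimensional")
        if self.matrix.shape[0] != len(self.labels):
            raise LabelError("row count does not match number of labels")
        if self.matrix.shape[1] < 1:
            raise ValueError("representation must have at least one neuron")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("representation matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    @property
    def name(self) -> str:
        return f"{self.model_tag}:{self.layer_tag}"


@dataclass
class ResidueRepresentation:
    """Per-residue vectors (l_s x D) for a single sequence."""

    label: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("residue representation must be a nonempty matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("residue representation contains non-finite entries")


@dataclass
class AttentionHeadMatrix:
    """Raw N x N column attention for one (layer, head); not symmetric."""

    labels: tuple[str, ...]
    layer: int
    head: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("attention matrix must be square and match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attention matrix contains non-finite entries")
        if self.layer < 1 or self.head < 1:
            raise ValueError("layer and head are 1-based positive integers")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def mean_pool(rep: ResidueRepresentation) -> np.ndarray:
    """Average per-residue vectors over sequence length -> one D-vector."""
    return rep.matrix.mean(axis=0)


def onehot_composition(seqs: SequenceSet | AlignedFamily) -> RepresentationSet:
    """Relative amino-acid frequency vector per sequence (rows sum to 1).

    Aligned input is degapped first: composition describes the protein, not
    the alignment, so gaps appear in neither numerator nor denominator.
    """
    if isinstance(seqs, AlignedFamily):
        rows = [row.replace(seqs.gap_char, "") for row in seqs.rows]
        labels = seqs.labels
    else:
        rows = list(seqs.sequences)
        labels = seqs.labels
    index = {aa: i for i, aa in enumerate(WORKING_ALPHABET)}
    mat = np.zeros((len(rows), len(WORKING_ALPHABET)))
    for r, (label, seq) in enumerate(zip(labels, rows)):
        if not seq:
            raise EmptySequenceError(f"sequence {label!r} is empty after degapping")
        for ch in seq:
            mat[r, index[ch]] += 1.0
        mat[r] /= len(seq)
    return RepresentationSet(labels, mat, model_tag="onehot", layer_tag="composition")


def pairwise_euclidean(reps: RepresentationSet, kind: str | None = None) -> DistanceMatrix:
    """Euclidean distance between every pair of representation rows."""
    if reps.n < 2:
        raise ValueError("need at least two sequences for pairwise distances")
    values = squareform(pdist(reps.matrix, metric="euclidean"))
    if kind is None:
        kind = "onehot" if reps.model_tag == "onehot" else "embedding"
    return DistanceMatrix(reps.labels, values, kind)


def average_attention_stack(stack: np.ndarray) -> np.ndarray:
    """Average a raw N x N x L per-column attention stack over alignment length."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("attention stack must be N x N x L")
    return stack.mean(axis=2)


def symmetrize_column_attention(att: AttentionHeadMatrix) -> DistanceMatrix:
    """Symmetrize length-averaged column attention as A + A^T."""
    sym = att.values + att.values.T
    return DistanceMatrix(att.labels, sym, "attention_similarity")


def mask_neurons(reps: RepresentationSet, keep: NeuronSet) -> RepresentationSet:
    """Restrict a representation to the kept neuron columns (ascending order)."""
    if len(keep) == 0:
        raise ValueError("keep set must be nonempty")
    idx = keep.as_array()
    if idx.max() >= reps.d:
        raise IndexError(
            f"neuron index {idx.max()} out of range for D={reps.d}"
        )
    return RepresentationSet(
        reps.labels,
        reps.matrix[:, idx],
        model_tag=reps.model_tag,
        layer_tag=f"{reps.layer_tag}|mask{len(keep)}",
    )


# ---------------------------------------------------------------------------
# Array-container I/O (one .npy per matrix plus a JSON label manifest)
# ---------------------------------------------------------------------------


def save_representation_sets(
    reps: Sequence[RepresentationSet], out_dir: str | Path
) -> Path:
    """Write representation sets as .npy files plus ``manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = reps[0].labels
    entries = []
    for rep in reps:
        if rep.labels != labels:
            raise LabelError("all representation sets must share one label order")
        fname = f"{rep.model_tag}__{rep.layer_tag}.npy".replace("/", "_")
        np.save(out_dir / fname, rep.matrix)
        entries.append(
            {"model_tag": rep.model_tag, "layer_tag": rep.layer_tag, "file": fname}
        )
    manifest = {"labels": list(labels), "entries": entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def load_representation_sets(in_dir: str | Path) -> list[RepresentationSet]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    labels = tuple(manifest["labels"])
    return [
        RepresentationSet(
            labels,
            np.load(in_dir / e["file"]),
            model_tag=e["model_tag"],
            layer_tag=e["layer_tag"],
        )
        for e in manifest["entries"]
    ]


def save_attention_heads(
    atts: Sequence[AttentionHeadMatrix], out_dir: str | Path
) -> Path:
    """Write attention head matrices as .npy files plus ``manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = atts[0].labels
    entries = []
    for att in atts:
        if att.labels != labels:
            raise LabelError("all attention matrices must share one label order")
        fname = f"L{att.layer}H{att.head}.npy"
        np.save(out_dir / fname, att.values)
        entries.append({"layer": att.layer, "head": att.head, "file": fname})
    manifest = {"labels": list(labels), "entries": entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def load_attention_heads(in_dir: str | Path) -> list[AttentionHeadMatrix]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    labels = tuple(manifest["labels"])
    return [
        AttentionHeadMatrix(
            labels, e["layer"], e["head"], np.load(in_dir / e["file"])
        )
        for e in manifest["entries"]
    ]
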