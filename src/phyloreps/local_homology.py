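"""Local homolog similarity: Jaccard overlap of k-nearest-neighbour sets.

For a reference sequence, the K nearest neighbours are found twice — once by
patristic distance in the tree and once by Euclidean distance in a
representation space — and compared by the Jaccard coefficient
|intersection| / |union| (LHS).  Scores are binned into four categories:
disagree (0), low (0, 0.5], high (0.5, 1), and agree (exactly 1), which
partition [0, 1].  Tables report the percentage of references per category
for each representation and K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .family_io import DistanceMatrix, LabelError
from .representation_spaces import RepresentationSet, pairwise_euclidean

CATEGORIES = ("disagree", "low", "high", "agree")


@dataclass
class LHSRecord:
    reference: str
    K: int
    set_tree: frozenset
    set_rep: frozenset
    score: float
    category: str


def knn_from_matrix(m: DistanceMatrix, reference: str, K: int) -> frozenset:
    """The K non-reference labels nearest to ``reference`` (ties by label)."""
    if not 1 <= K <= m.n - 1:
        raise ValueError(f"K={K} out of range for N={m.n}")
    ref_idx = m.index_of(reference)
    others = sorted(
        ((m.values[ref_idx, i], label) for i, label in enumerate(m.labels)
         if label != reference),
        key=lambda t: (t[0], t[1]),
    )
    return frozenset(label for _, label in others[:K])


def lhs(a: Iterable, b: Iterable) -> float:
    """Jaccard similarity |a & b| / |a | b| between two label sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("LHS requires two nonempty sets")
    return len(a & b) / len(a | b)


def categorize_lhs(score: float) -> str:
    """Map an LHS score to disagree / low / high / agree."""
    if not 0 <= score <= 1:
        raise ValueError(f"LHS score {score} outside [0, 1]")
    if score == 0:
        return "disagree"
    if score <= 0.5:
        return "low"
    if score < 1:
        return "high"
    return "agree"


def lhs_records(
    m_lg: DistanceMatrix, m_rep: DistanceMatrix, K: int
) -> list[LHSRecord]:
    """One LHS record per reference sequence at neighbourhood size K."""
    if set(m_lg.labels) != set(m_rep.labels):
        raise LabelError("matrices do not share a label set")
    records = []
    for reference in m_lg.labels:
        set_tree = knn_from_matrix(m_lg, reference, K)
        set_rep = knn_from_matrix(m_rep, reference, K)
        score = lhs(set_tree, set_rep)
        records.append(
            LHSRecord(reference, K, set_tree, set_rep, score, categorize_lhs(score))
        )
    return records


def _rep_name_and_matrix(rep) -> tuple[str, DistanceMatrix]:
    if isinstance(rep, DistanceMatrix):
        return rep.kind, rep
    if isinstance(rep, RepresentationSet):
        return rep.name, pairwise_euclidean(rep)
    raise TypeError(f"cannot interpret {type(rep).__name__} as a representation")


def lhs_table(
    m_lg: DistanceMatrix,
    reps: Sequence[RepresentationSet | DistanceMatrix],
    Ks: Sequence[int] = (5, 10, 20),
) -> pd.DataFrame:
    """Category percentages per (representation, K), every sequence as reference.

    All four categories are reported even when empty; percentages sum to 100
    before rounding.
    """
    rows = []
    for rep in reps:
        name, m_rep = _rep_name_and_matrix(rep)
        for K in Ks:
            records = lhs_records(m_lg, m_rep, K)
            counts = {c: 0 for c in CATEGORIES}
            for rec in records:
                counts[rec.category] += 1
            n = len(records)
            row = {"representation": name, "K": K, "n_references": n}
            for c in CATEGORIES:
                row[f"pct_{c}"] = 100.0 * counts[c] / n
            rows.append(row)
    cols = ["representation", "K"] + [f"pct_{c}" for c in CATEGORIES] + ["n_references"]
    return pd.DataFrame(rows, columns=cols)
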