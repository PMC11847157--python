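"""Evolutionary Similarity Score (ESS) and distance-scale analyses.

ESS is the correlation — Spearman's rho and/or Pearson's r — between the
strict upper triangles of two labelled distance matrices, typically a
patristic reference matrix and an embedding-space distance matrix.  Only the
upper triangle enters the correlation: the diagonal is identically zero and
the lower triangle duplicates the upper, so both would artificially inflate
agreement.

Beyond the full-matrix score, three per-reference samplings probe different
evolutionary scales:

* broad — 10 sequences evenly spaced over the sorted distances from a
  reference, spanning the closest to the farthest homolog;
* fine — the 10 closest sequences, probing the finest resolvable scale;
* all — every other sequence.

Per-dataset summaries average the per-reference correlations, and groups can
be stratified by the mean and variance of their member distances to isolate
recurring tree motifs (close vs remote homologs, low vs high divergence).

A shuffling stimulus provides the chance-level null: within each sequence,
random position pairs are swapped floor(0.8 * L) times, destroying residue
order while preserving composition exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .family_io import AlignedFamily, DistanceMatrix, LabelError, SequenceSet

Method = Literal["spearman", "pearson", "both"]

MEAN_BIN_NAMES = ("close", "intermediate", "remote")
VAR_BIN_NAMES = ("not_divergent", "moderately_divergent", "highly_divergent")


class DegenerateInputError(ValueError):
    """Raised when an input has zero variance where correlation is required."""


@dataclass
class ESSResult:
    """ESS between two distance matrices.

    ``degenerate`` flags a zero-variance upper triangle; coefficients are then
    NaN rather than a silent zero, so they can never leak into averages or
    win counts unnoticed.
    """

    rho: float
    r: float
    n_pairs: int
    matrix_a_kind: str
    matrix_b_kind: str
    context: str = ""
    degenerate: bool = False


@dataclass
class GroupSample:
    """A reference sequence and a member set drawn around it."""

    reference: str
    members: tuple[str, ...]
    kind: str  # broad | fine | all | knn
    mean_dist: float
    var_dist: float

    def __post_init__(self) -> None:
        if self.reference in self.members:
            raise LabelError("reference must not appear among members")
        if len(set(self.members)) != len(self.members):
            raise LabelError("duplicate members in group sample")


@dataclass(frozen=True)
class StratumLabel:
    mean_bin: str
    var_bin: str


def ess(
    a: DistanceMatrix,
    b: DistanceMatrix,
    method: Method = "both",
    context: str = "",
) -> ESSResult:
    """Correlate the strict upper triangles of two labelled matrices.

    ``b`` is reordered to ``a``'s label order first.  Spearman uses average
    ranks for ties.  A zero-variance triangle on either side yields a result
    flagged degenerate with NaN coefficients.
    """
    if set(a.labels) != set(b.labels):
        raise LabelError("matrices do not share a label set")
    if a.n < 3:
        raise ValueError("ESS needs at least 3 sequences")
    x = a.condensed()
    y = b.reorder(a.labels).condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ESSResult(
            math.nan, math.nan, len(x), a.kind, b.kind, context, degenerate=True
        )
    rho = r = math.nan
    if method in ("spearman", "both"):
        rho = float(stats.spearmanr(x, y).statistic)
    if method in ("pearson", "both"):
        r = float(stats.pearsonr(x, y).statistic)
    return ESSResult(rho, r, len(x), a.kind, b.kind, context)


def shuffle_stimulus(
    seqs: SequenceSet | AlignedFamily, fraction: float = 0.8, seed: int = 0
):
    """Swap-shuffle every sequence in place of the chance-level stimulus.

    For a sequence of length L, floor(fraction * L) swap operations are
    performed; each exchanges the characters at two uniformly chosen distinct
    positions (one RNG draw per swap).  Aligned input is shuffled at aligned
    length, gap characters included, so per-row composition — gaps and all —
    is preserved exactly.  Deterministic given ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = seqs.rows if isinstance(seqs, AlignedFamily) else seqs.sequences

    shuffled = []
    for row in rows:
        length = len(row)
        if length < 2:
            raise ValueError("cannot shuffle a sequence of length < 2")
        chars = list(row)
        for _ in range(int(fraction * length)):
            i, j = rng.choice(length, size=2, replace=False)
            chars[i], chars[j] = chars[j], chars[i]
        shuffled.append("".join(chars))

    if isinstance(seqs, AlignedFamily):
        return AlignedFamily(
            family_id=f"{seqs.family_id}|shuffled",
            labels=seqs.labels,
            rows=tuple(shuffled),
            alphabet=seqs.alphabet,
            gap_char=seqs.gap_char,
        )
    return SequenceSet(labels=seqs.labels, sequences=tuple(shuffled))


def _sorted_others(m: DistanceMatrix, reference: str) -> tuple[list[str], np.ndarray]:
    """Non-reference labels sorted by distance ascending, ties by label."""
    ref_idx = m.index_of(reference)
    others = [
        (m.values[ref_idx, i], label)
        for i, label in enumerate(m.labels)
        if label != reference
    ]
    others.sort(key=lambda t: (t[0], t[1]))
    labels = [label for _, label in others]
    dists = np.array([d for d, _ in others])
    return labels, dists


def _group(reference: str, labels: Sequence[str], dists: np.ndarray, kind: str):
    return GroupSample(
        reference=reference,
        members=tuple(labels),
        kind=kind,
        mean_dist=float(np.mean(dists)),
        var_dist=float(np.var(dists)),
    )


def broad_sample(m_lg: DistanceMatrix, reference: str, m: int = 10) -> GroupSample:
    """``m`` sequences evenly spaced over sorted distances from the reference.

    Sorted ranks 0..N-2 are sampled at round(i * (N-2) / (m-1)) for
    i = 0..m-1, which always includes the closest and the farthest sequence.
    """
    if m < 2:
        raise ValueError("broad sample needs m >= 2")
    labels, dists = _sorted_others(m_lg, reference)
    if len(labels) < m:
        raise ValueError(f"need at least {m} non-reference sequences")
    top = len(labels) - 1
    picks = [int(math.floor(i * top / (m - 1) + 0.5)) for i in range(m)]
    return _group(
        reference, [labels[k] for k in picks], dists[picks], "broad"
    )


def fine_sample(m_lg: DistanceMatrix, reference: str, m: int = 10) -> GroupSample:
    """The ``m`` closest sequences to the reference (ties by label order)."""
    labels, dists = _sorted_others(m_lg, reference)
    if len(labels) < m:
        raise ValueError(f"need at least {m} non-reference sequences")
    return _group(reference, labels[:m], dists[:m], "fine")


def all_sample(m_lg: DistanceMatrix, reference: str) -> GroupSample:
    """Every non-reference sequence as one group."""
    labels, dists = _sorted_others(m_lg, reference)
    return _group(reference, labels, dists, "all")


def group_correlation(
    m_lg: DistanceMatrix,
    m_plm: DistanceMatrix,
    g: GroupSample,
    method: str = "pearson",
) -> float:
    """Correlate reference-to-member distances between the two matrices.

    Returns NaN for a degenerate (zero-variance) vector on either side.
    """
    if len(g.members) < 3:
        raise ValueError("group correlation needs at least 3 members")
    i_lg = m_lg.index_of(g.reference)
    i_pl = m_plm.index_of(g.reference)
    x = np.array([m_lg.values[i_lg, m_lg.index_of(l)] for l in g.members])
    y = np.array([m_plm.values[i_pl, m_plm.index_of(l)] for l in g.members])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def dataset_scale_summary(
    m_lg: DistanceMatrix,
    m_plm: DistanceMatrix,
    method: str = "pearson",
    m: int = 10,
) -> dict:
    """Mean per-reference correlation at broad, fine, and all scales.

    Every sequence serves as the reference once.  References degenerate at
    any scale are excluded from all three means and counted in
    ``n_excluded`` so the three scales stay commensurable.
    """
    if m_lg.n < m + 2:
        raise ValueError(f"need at least {m + 2} sequences for scale summary")
    if set(m_lg.labels) != set(m_plm.labels):
        raise LabelError("matrices do not share a label set")
    rows = {"broad": [], "fine": [], "all": []}
    n_excluded = 0
    for reference in m_lg.labels:
        groups = {
            "broad": broad_sample(m_lg, reference, m),
            "fine": fine_sample(m_lg, reference, m),
            "all": all_sample(m_lg, reference),
        }
        coeffs = {
            scale: group_correlation(m_lg, m_plm, g, method)
            for scale, g in groups.items()
        }
        if any(math.isnan(c) for c in coeffs.values()):
            n_excluded += 1
            continue
        for scale, c in coeffs.items():
            rows[scale].append(c)
    if not rows["broad"]:
        raise DegenerateInputError("all references degenerate in scale summary")
    return {
        "broad": float(np.mean(rows["broad"])),
        "fine": float(np.mean(rows["fine"])),
        "all": float(np.mean(rows["all"])),
        "n_references": len(rows["broad"]),
        "n_excluded": n_excluded,
    }


def collect_groups(
    m_lg: DistanceMatrix, m: int = 10, kinds: Sequence[str] = ("broad", "fine")
) -> list[GroupSample]:
    """Broad and/or fine groups for every reference sequence."""
    samplers = {"broad": broad_sample, "fine": fine_sample}
    groups = []
    for reference in m_lg.labels:
        for kind in kinds:
            groups.append(samplers[kind](m_lg, reference, m))
    return groups


def stratify_groups(
    groups: Sequence[GroupSample],
    mean_edges: Sequence[float] | None = None,
    var_edges: Sequence[float] | None = None,
) -> list[tuple[GroupSample, StratumLabel]]:
    """Assign each group a (mean, variance) stratum.

    Default edges are pooled tertiles of group means and variances.  Bins are
    left-closed / right-open, with the last bin right-closed.
    """
    if not groups:
        return []
    means = np.array([g.mean_dist for g in groups])
    variances = np.array([g.var_dist for g in groups])
    if mean_edges is None:
        mean_edges = np.quantile(means, [1 / 3, 2 / 3])
    if var_edges is None:
        var_edges = np.quantile(variances, [1 / 3, 2 / 3])
    mean_edges = np.asarray(mean_edges, dtype=float)
    var_edges = np.asarray(var_edges, dtype=float)
    for edges in (mean_edges, var_edges):
        if len(edges) != 2 or edges[0] > edges[1]:
            raise ValueError("edges must be two non-decreasing reals")
    out = []
    for g in groups:
        mi = int(np.searchsorted(mean_edges, g.mean_dist, side="right"))
        vi = int(np.searchsorted(var_edges, g.var_dist, side="right"))
        out.append((g, StratumLabel(MEAN_BIN_NAMES[mi], VAR_BIN_NAMES[vi])))
    return out


def win_counts(per_dataset_ess: pd.DataFrame) -> dict:
    """Per-representation counts of datasets won (strict ESS maximum).

    Expects columns ``dataset``, ``representation``, ``rho``, ``r``.  For each
    metric, a representation wins a dataset when it attains the unique
    maximum; ties award no win and are counted separately.
    """
    df = per_dataset_ess
    if df.empty:
        raise ValueError("empty ESS table")
    result = {}
    for metric in ("rho", "r"):
        wins: dict[str, int] = {rep: 0 for rep in df["representation"].unique()}
        ties = 0
        for dataset, sub in df.groupby("dataset"):
            if len(sub) < 2:
                raise ValueError(f"dataset {dataset!r} has fewer than 2 representations")
            vals = sub[metric].to_numpy(float)
            if np.any(np.isnan(vals)):
                raise DegenerateInputError(
                    f"dataset {dataset!r} has a degenerate {metric} entry"
                )
            best = vals.max()
            winners = sub.loc[sub[metric] == best, "representation"].tolist()
            if len(winners) == 1:
                wins[winners[0]] += 1
            else:
                ties += 1
        result[metric] = {"wins": wins, "ties": ties}
    return result


def paired_rank_test(x, y, alternative: str = "greater"):
    """Thin wrapper: Wilcoxon signed-rank test for paired ESS distributions."""
    return stats.wilcoxon(x, y, alternative=alternative)


def two_sample_ks_test(x, y):
    """Thin wrapper: two-sample Kolmogorov-Smirnov test for ESS distributions."""
    return stats.ks_2samp(x, y)
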