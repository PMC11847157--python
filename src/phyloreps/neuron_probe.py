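"""Elastic-net "evolution probe": neuron saliency for evolutionary distance.

The probe asks where in an embedding space the evolutionary signal lives.
For sampled sequence pairs (i, j), the feature vector is the element-wise
absolute difference |z_i - z_j| over neurons that pass a variance filter,
and the target is the patristic distance between the two sequences.  An
elastic net (squared error plus L1 and L2 penalties, strengths chosen by
cross-validation on the training split) is fitted on a 70/30 split, repeated
over independent pair samples, and each neuron's saliency is the sum of its
absolute coefficients across runs.

Neurons are then binned by saliency — top 10/25/50/75% and bottom 25% —
under either of two schemes: *mass* (smallest prefix holding the given share
of total saliency, matching a "neurons constituting X% of the weights"
definition) or *count* (first ceil(X% * D') neurons).  Ablation recomputes
the ESS using only the neurons of one bin, validating the scoring: salient
bins should track the patristic matrix, bottom bins should not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import train_test_split

from .family_io import DistanceMatrix, LabelError
from .representation_spaces import (
    NeuronSet,
    RepresentationSet,
    mask_neurons,
    pairwise_euclidean,
)
from .rsa_ess import ESSResult, ess

BIN_NAMES = ("top10", "top25", "top50", "top75", "bottom25")
TOP_FRACTIONS = {"top10": 0.10, "top25": 0.25, "top50": 0.50, "top75": 0.75}


@dataclass
class ProbeConfig:
    """Configuration of the evolution probe.

    Defaults: 9000 sampled pairs, 70/30 train/test split, 10 repeats, and a
    variance filter keeping neurons above the 20th percentile of activation
    variance.  The cross-validation grid spans mixing ratios 0.1/0.5/0.9 and
    overall penalty strengths log-spaced over 1e-4..1e1.
    """

    n_pairs: int = 9000
    train_fraction: float = 0.7
    n_runs: int = 10
    variance_percentile: float = 20.0
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    alphas: tuple[float, ...] = tuple(np.logspace(-4, 1, 10))
    cv_folds: int = 5
    seed: int = 0
    bin_scheme: str = "mass"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 <= self.variance_percentile < 100:
            raise ValueError("variance_percentile must be in [0, 100)")
        if self.bin_scheme not in ("mass", "count"):
            raise ValueError("bin_scheme must be 'mass' or 'count'")


@dataclass
class ProbeRun:
    """One fitted repeat over the kept neurons.

    ``coefficients`` are on the original feature scale (usable for
    prediction from raw |z_i - z_j| features); ``std_coefficients`` are on
    the standardized scale and measure each neuron's predictive importance
    independently of its activation scale — saliency aggregates these, since
    dividing by near-zero feature scales would otherwise hand the largest
    back-transformed coefficients to the least informative neurons.
    """

    coefficients: np.ndarray
    std_coefficients: np.ndarray
    intercept: float
    r2_test: float
    alpha: float
    l1_ratio: float
    degenerate: bool = False


@dataclass
class ProbeResult:
    kept_neurons: NeuronSet
    runs: list[ProbeRun]
    saliency: np.ndarray  # over kept neurons, same order as kept_neurons.indices
    bins: dict[str, NeuronSet]  # original neuron index space
    ablation: dict[str, ESSResult]
    scheme: str

    @property
    def r2_per_run(self) -> list[float]:
        return [run.r2_test for run in self.runs]

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_per_run))

    def to_dict(self) -> dict:
        """JSON-serializable summary (deterministic key order left to caller)."""
        return {
            "kept_neurons": list(self.kept_neurons.indices),
            "scheme": self.scheme,
            "runs": [
                {
                    "r2_test": run.r2_test,
                    "alpha": run.alpha,
                    "l1_ratio": run.l1_ratio,
                    "intercept": run.intercept,
                    "degenerate": run.degenerate,
                }
                for run in self.runs
            ],
            "saliency": [float(s) for s in self.saliency],
            "bins": {name: list(ns.indices) for name, ns in self.bins.items()},
            "ablation": {
                name: {"rho": res.rho, "r": res.r, "n_pairs": res.n_pairs}
                for name, res in self.ablation.items()
            },
        }


def variance_filter(reps: RepresentationSet, percentile: float = 20.0) -> NeuronSet:
    """Keep neurons whose activation variance exceeds the given percentile.

    Variance uses denominator N; the threshold is the linear-interpolation
    percentile of per-neuron variances, and the comparison is strict.  If all
    variances are identical every neuron is kept, with a warning.
    """
    if reps.n < 2:
        raise ValueError("variance filter needs at least 2 sequences")
    variances = reps.matrix.var(axis=0, ddof=0)
    if np.ptp(variances) == 0:
        warnings.warn(
            "all neuron variances identical; keeping every neuron",
            stacklevel=2,
        )
        return NeuronSet(tuple(range(reps.d)))
    threshold = np.percentile(variances, percentile)
    kept = np.flatnonzero(variances > threshold)
    return NeuronSet(tuple(int(i) for i in kept))


def sample_pairs(n_sequences: int, count: int, seed: int) -> np.ndarray:
    """Uniformly sample ``count`` distinct unordered pairs (i < j)."""
    iu = np.triu_indices(n_sequences, k=1)
    universe = len(iu[0])
    if count > universe:
        raise ValueError(f"count={count} exceeds pair universe {universe}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(universe, size=count, replace=False)
    return np.column_stack((iu[0][picks], iu[1][picks]))


def pair_features(
    reps: RepresentationSet,
    keep: NeuronSet,
    pairs: np.ndarray,
    m_lg: DistanceMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """|z_i - z_j| over kept neurons per pair, with patristic targets."""
    if len(keep) == 0:
        raise ValueError("keep set must be nonempty")
    if set(reps.labels) != set(m_lg.labels):
        raise LabelError("representation and matrix labels differ")
    m = m_lg.reorder(reps.labels)
    z = reps.matrix[:, keep.as_array()]
    i, j = pairs[:, 0], pairs[:, 1]
    features = np.abs(z[i] - z[j])
    targets = m.values[i, j]
    return features, targets


def fit_probe(
    features: np.ndarray,
    targets: np.ndarray,
    cfg: ProbeConfig,
    run_seed: int,
) -> ProbeRun:
    """Fit one elastic-net repeat on a fresh train/test split.

    Features are standardized on the training split only; reported
    coefficients are transformed back to the original feature scale.  The
    held-out coefficient of determination is computed on the test split.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if np.ptp(targets) == 0:
        zeros = np.zeros(features.shape[1])
        return ProbeRun(
            zeros, zeros.copy(), float(targets.mean()), math.nan,
            math.nan, math.nan, degenerate=True,
        )
    x_train, x_test, y_train, y_test = train_test_split(
        features,
        targets,
        train_size=cfg.train_fraction,
        random_state=int(run_seed) % (2**32),
    )
    if len(y_train) < 10:
        raise ValueError("need at least 10 training rows")
    mean = x_train.mean(axis=0)
    scale = x_train.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    xs_train = (x_train - mean) / scale
    model = ElasticNetCV(
        l1_ratio=list(cfg.l1_ratios),
        alphas=list(cfg.alphas),
        cv=cfg.cv_folds,
        max_iter=5000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter at tiny alphas
        model.fit(xs_train, y_train)
    coef = model.coef_ / scale
    intercept = float(model.intercept_ - np.dot(model.coef_, mean / scale))
    pred = x_test @ coef + intercept
    ss_res = float(np.sum((y_test - pred) ** 2))
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return ProbeRun(
        coef, model.coef_.copy(), intercept, r2,
        float(model.alpha_), float(model.l1_ratio_),
    )


def aggregate_saliency(runs: Sequence[ProbeRun | np.ndarray]) -> np.ndarray:
    """Per-neuron saliency: sum of |coefficient| across runs.

    ``ProbeRun`` inputs contribute their standardized-scale coefficients;
    raw arrays are used as given.
    """
    coefs = [
        np.asarray(run.std_coefficients if isinstance(run, ProbeRun) else run, float)
        for run in runs
    ]
    if not coefs:
        raise ValueError("no runs to aggregate")
    shapes = {c.shape for c in coefs}
    if len(shapes) != 1:
        raise ValueError("runs do not share a kept-neuron index space")
    return np.sum(np.abs(coefs), axis=0)


def bin_neurons(saliency: np.ndarray, scheme: str = "mass") -> dict[str, np.ndarray]:
    """Bin neurons (indices into the saliency vector) by descending saliency.

    mass: topX is the smallest prefix whose saliency sum reaches X% of the
    total; bottom25 is the largest suffix holding at most 25% of the total
    (possibly empty).  count: topX is the first ceil(X% * D') neurons and
    bottom25 the last ceil(25% * D').  Ties are broken by neuron index; top
    bins are nested under both schemes.
    """
    saliency = np.asarray(saliency, dtype=float)
    if np.any(saliency < 0):
        raise ValueError("saliency must be nonnegative")
    total = saliency.sum()
    if total == 0:
        raise ValueError("all-zero saliency cannot be binned")
    order = np.argsort(-saliency, kind="stable")  # desc, ties by index
    d = len(saliency)
    bins: dict[str, np.ndarray] = {}
    if scheme == "mass":
        cum = np.cumsum(saliency[order])
        for name, frac in TOP_FRACTIONS.items():
            k = int(np.searchsorted(cum, frac * total, side="left")) + 1
            bins[name] = np.sort(order[:k])
        rev_cum = np.cumsum(saliency[order][::-1])
        j = int(np.searchsorted(rev_cum, 0.25 * total, side="right"))
        bins["bottom25"] = np.sort(order[d - j:]) if j > 0 else np.array([], int)
    elif scheme == "count":
        for name, frac in TOP_FRACTIONS.items():
            k = math.ceil(frac * d)
            bins[name] = np.sort(order[:k])
        k = math.ceil(0.25 * d)
        bins["bottom25"] = np.sort(order[d - k:])
    else:
        raise ValueError("scheme must be 'mass' or 'count'")
    return bins


def ablation_ess(
    reps: RepresentationSet, bin_neuron_set: NeuronSet, m_lg: DistanceMatrix
) -> ESSResult:
    """ESS of the patristic matrix against distances from one neuron bin only."""
    masked = mask_neurons(reps, bin_neuron_set)
    return ess(m_lg, pairwise_euclidean(masked), context="ablation")


def evolution_probe(
    reps: RepresentationSet, m_lg: DistanceMatrix, cfg: ProbeConfig | None = None
) -> ProbeResult:
    """Run the full probe: filter, repeated fits, saliency, bins, ablation."""
    cfg = cfg or ProbeConfig()
    kept = variance_filter(reps, cfg.variance_percentile)
    universe = reps.n * (reps.n - 1) // 2
    count = cfg.n_pairs
    if count > universe:
        warnings.warn(
            f"pair universe {universe} smaller than n_pairs={cfg.n_pairs}; "
            "using every pair",
            stacklevel=2,
        )
        count = universe
    run_seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_runs)
    runs = []
    for r in range(cfg.n_runs):
        pairs = sample_pairs(reps.n, count, int(run_seeds[2 * r]))
        features, targets = pair_features(reps, kept, pairs, m_lg)
        runs.append(fit_probe(features, targets, cfg, int(run_seeds[2 * r + 1])))
    usable = [run for run in runs if not run.degenerate]
    if not usable:
        raise ValueError("all probe runs degenerate (zero-variance targets)")
    saliency = aggregate_saliency(usable)
    kept_arr = kept.as_array()
    raw_bins = bin_neurons(saliency, cfg.bin_scheme)
    bins = {
        name: NeuronSet(tuple(int(i) for i in kept_arr[idx]))
        for name, idx in raw_bins.items()
    }
    ablation = {
        name: ablation_ess(reps, ns, m_lg)
        for name, ns in bins.items()
        if len(ns) > 0
    }
    return ProbeResult(kept, runs, saliency, bins, ablation, cfg.bin_scheme)


def bin_overlap_counts(bin_sets: Sequence[NeuronSet]) -> np.ndarray:
    """Pairwise intersection sizes between neuron bins (e.g. across families)."""
    n = len(bin_sets)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            out[i, j] = len(bin_sets[i].intersection(bin_sets[j]))
    return out
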