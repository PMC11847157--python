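"""Synthetic trees, alignments, embeddings, and attention for pipeline tests.

Everything downstream is exercised on generated data with known ground
truth:

* Yule (pure-birth) tree topologies with independent exponential branch
  lengths;
* sequences evolved along the tree under a symmetric 20-state substitution
  process with Poisson indel events (geometric lengths), yielding alignments
  whose gap fraction can be calibrated into the low-gap (<= 20%) or high-gap
  (>= 70%) regime;
* planted embedding spaces: classical multidimensional scaling coordinates
  of a (possibly distorted) patristic matrix written into a random "salient"
  neuron subset, with Gaussian noise elsewhere — so pairwise Euclidean
  distance is a noisy monotone image of patristic distance and the signal is
  localised to a known neuron set;
* attention matrices whose symmetrized form correlates positively or
  negatively with patristic distance, with an antisymmetric perturbation
  that cancels exactly under symmetrization.

All generators are deterministic given the config seed; each draws from its
own seeded stream so operations stay reproducible independently of call
order.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .family_io import (
    AMINO_ACIDS,
    AlignedFamily,
    DistanceMatrix,
    GAP_CHAR,
    PhyloTree,
    average_matrices,
    degap,
    gap_percentage,
    patristic_matrix,
    write_alignment,
)
from .representation_spaces import (
    AttentionHeadMatrix,
    NeuronSet,
    RepresentationSet,
    onehot_composition,
    save_attention_heads,
    save_representation_sets,
)

_DISTORTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "sqrt": np.sqrt,
    "log1p": np.log1p,
}

# Per-operation RNG stream tags, so each generator has its own substream.
_STREAM_TREE = 11
_STREAM_ALIGNMENT = 22
_STREAM_EMBED = 33
_STREAM_ATTENTION = 44
_STREAM_JITTER = 55


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Branch lengths are exponential with mean ``1/birth_rate`` (expected
    substitutions per site scale as ``subst_rate`` times branch length).
    ``salient_fraction`` of the ``embed_dim`` neurons carry the planted tree
    signal; ``noise_sigma`` scales both the jitter on salient coordinates
    and the amplitude of pure-noise neurons.
    """

    n_leaves: int = 80
    seq_length: int = 150
    birth_rate: float = 2.0
    subst_rate: float = 0.3
    indel_rate: float = 0.001
    mean_indel_len: float = 3.0
    embed_dim: int = 256
    salient_fraction: float = 0.1
    noise_sigma: float = 0.25
    distortion: str = "identity"
    attention_sign: str = "positive"
    tree_jitter_sigma: float = 0.1
    n_tree_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 4:
            raise ValueError("n_leaves must be >= 4")
        if not 0 < self.salient_fraction <= 1:
            raise ValueError("salient_fraction must be in (0, 1]")
        for name in ("birth_rate", "subst_rate", "indel_rate", "mean_indel_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.distortion not in _DISTORTIONS:
            raise ValueError(f"unknown distortion {self.distortion!r}")
        if self.attention_sign not in ("positive", "negative"):
            raise ValueError("attention_sign must be 'positive' or 'negative'")


class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self):
        self.children: list[_Node] = []
        self.length: float = 0.0
        self.label: str | None = None


def _newick(node: _Node) -> str:
    if not node.children:
        return f"{node.label}:{node.length!r}"
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}):{node.length!r}"


def simulate_tree(cfg: SyntheticConfig) -> PhyloTree:
    """Yule topology with iid exponential branch lengths (mean 1/birth_rate)."""
    rng = np.random.default_rng([cfg.seed, _STREAM_TREE])
    root = _Node()
    root.children = [_Node(), _Node()]
    leaves = list(root.children)
    while len(leaves) < cfg.n_leaves:
        k = int(rng.integers(len(leaves)))
        node = leaves.pop(k)
        node.children = [_Node(), _Node()]
        leaves.extend(node.children)
    # Assign labels and branch lengths in preorder for determinism.
    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if node is not root:
            node.length = float(rng.exponential(1.0 / cfg.birth_rate))
        if not node.children:
            counter += 1
            node.label = f"t{counter:04d}"
        stack.extend(reversed(node.children))
    newick = f"({','.join(_newick(c) for c in root.children)});"
    return PhyloTree.from_newick(newick)


def jitter_tree(tree: PhyloTree, sigma: float, rng: np.random.Generator) -> PhyloTree:
    """Multiply every branch length by an iid log-normal factor.

    Emulates replicate tree inferences under different random seeds: same
    topology and leaf set, perturbed branch lengths.
    """
    clone = tree.tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length * rng.lognormal(0.0, sigma))
    return PhyloTree(clone)


def _substitute(residue_idx: int, rng: np.random.Generator) -> int:
    """Uniform draw over the 19 residues different from the current one."""
    k = int(rng.integers(19))
    return k if k < residue_idx else k + 1


def simulate_alignment(
    tree: PhyloTree, cfg: SyntheticConfig, indel_rate: float | None = None
) -> AlignedFamily:
    """Evolve sequences down the tree with substitutions and indels.

    The root sequence is uniform over the 20 amino acids.  Along a branch of
    length t each present site substitutes with probability 1 - exp(-r t) to
    a uniformly chosen different residue; indel events arise as a Poisson
    process (rate ``indel_rate`` * t per site) with geometric lengths,
    insertions adding fresh alignment columns and deletions writing gaps.
    All-gap columns are dropped from the final alignment.
    """
    rate = cfg.indel_rate if indel_rate is None else indel_rate
    for attempt in range(5):
        fam = _simulate_alignment_once(tree, cfg, rate, cfg.seed + 101 * attempt)
        if fam is not None:
            if attempt > 0:
                warnings.warn(
                    f"resampled alignment {attempt} time(s) to avoid an "
                    "all-gap sequence",
                    stacklevel=2,
                )
            return fam
    raise RuntimeError("could not simulate an alignment without all-gap rows")


def _simulate_alignment_once(
    tree: PhyloTree, cfg: SyntheticConfig, indel_rate: float, seed: int
) -> AlignedFamily | None:
    rng = np.random.default_rng([seed, _STREAM_ALIGNMENT])
    aa_count = len(AMINO_ACIDS)

    master: list[int] = list(range(cfg.seq_length))  # global column order
    next_col = cfg.seq_length
    root_seq = [
        (c, int(r)) for c, r in zip(master, rng.integers(aa_count, size=cfg.seq_length))
    ]

    node_seqs: dict[int, list[tuple[int, int]]] = {}
    root = tree.tree.seed_node
    node_seqs[id(root)] = root_seq
    leaf_rows: dict[str, dict[int, int]] = {}

    for node in tree.tree.preorder_node_iter():
        if node is root:
            seq = root_seq
        else:
            parent_seq = node_seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            seq = [entry for entry in parent_seq]

            # Substitutions on present (non-gap) sites.
            present = [k for k, (_, r) in enumerate(seq) if r >= 0]
            if present and cfg.subst_rate > 0 and t > 0:
                p_sub = 1.0 - math.exp(-cfg.subst_rate * t)
                hits = rng.random(len(present)) < p_sub
                for k, hit in zip(present, hits):
                    if hit:
                        col, r = seq[k]
                        seq[k] = (col, _substitute(r, rng))

            # Indel events: Poisson in the number of present sites.
            n_present = sum(1 for _, r in seq if r >= 0)
            if indel_rate > 0 and t > 0 and n_present > 0:
                n_events = int(rng.poisson(indel_rate * t * n_present))
                for _ in range(n_events):
                    length = int(rng.geometric(1.0 / cfg.mean_indel_len))
                    if rng.random() < 0.5:  # deletion
                        present = [k for k, (_, r) in enumerate(seq) if r >= 0]
                        if not present:
                            continue
                        start = int(rng.integers(len(present)))
                        for k in present[start:start + length]:
                            seq[k] = (seq[k][0], -1)
                    else:  # insertion
                        pos = int(rng.integers(len(seq) + 1))
                        if pos == 0:
                            m_idx = master.index(seq[0][0]) if seq else len(master)
                        else:
                            m_idx = master.index(seq[pos - 1][0]) + 1
                        residues = rng.integers(aa_count, size=length)
                        new_cols = list(range(next_col, next_col + length))
                        next_col += length
                        master[m_idx:m_idx] = new_cols
                        seq[pos:pos] = [
                            (c, int(r)) for c, r in zip(new_cols, residues)
                        ]
            node_seqs[id(node)] = seq
        if node.is_leaf():
            leaf_rows[node.taxon.label] = {c: r for c, r in seq if r >= 0}

    labels = tree.leaf_labels
    if any(not leaf_rows[label] for label in labels):
        return None
    used_cols = [c for c in master if any(c in leaf_rows[l] for l in labels)]
    rows = tuple(
        "".join(
            AMINO_ACIDS[leaf_rows[label][c]] if c in leaf_rows[label] else GAP_CHAR
            for c in used_cols
        )
        for label in labels
    )
    return AlignedFamily(
        family_id=f"synthetic_seed{seed}", labels=labels, rows=rows
    )


def calibrate_indel_rate(
    tree: PhyloTree,
    cfg: SyntheticConfig,
    target_gap: float,
    tol: float = 0.02,
    max_iter: int = 40,
) -> tuple[float, AlignedFamily]:
    """Search the indel rate whose realized gap fraction hits ``target_gap``.

    Gap fraction is monotone (up to simulation noise) in the indel rate for a
    fixed seed; a bracketing bisection converges to within ``tol`` (default
    two percentage points).  Returns the rate and the alignment it produces.
    """
    if not 0 < target_gap < 1:
        raise ValueError("target_gap must be in (0, 1)")

    def realized(rate: float) -> tuple[float, AlignedFamily]:
        fam = simulate_alignment(tree, cfg, indel_rate=rate)
        return gap_percentage(fam), fam

    lo, hi = 0.0, max(cfg.indel_rate, 0.05)
    gap_hi, fam_hi = realized(hi)
    grow = 0
    while gap_hi < target_gap and grow < 20:
        hi *= 2.0
        gap_hi, fam_hi = realized(hi)
        grow += 1
    if abs(gap_hi - target_gap) <= tol:
        return hi, fam_hi
    best_rate, best_fam, best_err = hi, fam_hi, abs(gap_hi - target_gap)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        gap_mid, fam_mid = realized(mid)
        err = abs(gap_mid - target_gap)
        if err < best_err:
            best_rate, best_fam, best_err = mid, fam_mid, err
        if err <= tol:
            return mid, fam_mid
        if gap_mid < target_gap:
            lo = mid
        else:
            hi = mid
    warnings.warn(
        f"calibration stopped at gap error {best_err:.3f} (target {target_gap})",
        stacklevel=2,
    )
    return best_rate, best_fam


def classical_mds(distances: np.ndarray, n_dims: int) -> np.ndarray:
    """Classical MDS coordinates, clamping negative eigenvalues to zero.

    Tree metrics are generally not Euclidean-realizable; clamping yields the
    closest low-rank Euclidean surrogate.
    """
    d2 = np.asarray(distances, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    k = min(n_dims, n)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    if n_dims > n:
        coords = np.hstack([coords, np.zeros((n, n_dims - n))])
    return coords


def simulate_embeddings(
    m_lg: DistanceMatrix, cfg: SyntheticConfig
) -> tuple[RepresentationSet, NeuronSet]:
    """Plant a (distorted) tree metric into a random salient neuron subset.

    MDS coordinates of ``distortion(m_lg)`` in ceil(salient_fraction * D)
    dimensions are written into uniformly chosen salient neurons; the
    remaining neurons carry zero-mean Gaussian noise with standard deviation
    ``noise_sigma`` times the median nonzero coordinate magnitude, and the
    salient coordinates receive additional Gaussian jitter of standard
    deviation ``noise_sigma``.
    """
    if np.ptp(m_lg.values) == 0:
        raise ValueError("degenerate (constant) distance matrix")
    rng = np.random.default_rng([cfg.seed, _STREAM_EMBED])
    d_dim = math.ceil(cfg.salient_fraction * cfg.embed_dim)
    if d_dim < 2:
        raise ValueError("salient subset must have at least 2 neurons")
    g = _DISTORTIONS[cfg.distortion]
    coords = classical_mds(g(m_lg.values), d_dim)
    n = m_lg.n
    salient = np.sort(rng.choice(cfg.embed_dim, size=d_dim, replace=False))
    matrix = np.zeros((n, cfg.embed_dim))
    matrix[:, salient] = coords
    if cfg.noise_sigma > 0:
        matrix[:, salient] += rng.normal(0.0, cfg.noise_sigma, size=(n, d_dim))
        nonzero = np.abs(coords[coords != 0])
        med = float(np.median(nonzero)) if nonzero.size else 1.0
        others = np.setdiff1d(np.arange(cfg.embed_dim), salient)
        if others.size:
            matrix[:, others] = rng.normal(
                0.0, cfg.noise_sigma * med, size=(n, others.size)
            )
    reps = RepresentationSet(
        m_lg.labels, matrix, model_tag="planted", layer_tag="output"
    )
    return reps, NeuronSet(tuple(int(i) for i in salient))


def multiplicative_noise_matrix(
    m_lg: DistanceMatrix, sigma: float, seed: int
) -> DistanceMatrix:
    """Distance matrix with symmetric log-normal multiplicative noise.

    Each upper-triangle entry is scaled by exp(sigma * eps - sigma^2 / 2)
    with eps standard normal, keeping entries positive and mean-preserving —
    the noise model behind the broad/fine/all scale-ordering checks.
    """
    rng = np.random.default_rng(seed)
    n = m_lg.n
    iu = np.triu_indices(n, k=1)
    factors = np.exp(sigma * rng.standard_normal(len(iu[0])) - 0.5 * sigma**2)
    values = np.zeros((n, n))
    values[iu] = m_lg.values[iu] * factors
    values += values.T
    return DistanceMatrix(m_lg.labels, values, "embedding")


def hamming_matrix(fam: AlignedFamily) -> DistanceMatrix:
    """Normalized Hamming distance between aligned rows (gaps as characters).

    Order-sensitive by construction: shuffling residues within rows changes
    it even though composition is preserved.
    """
    arr = np.frombuffer(
        "".join(fam.rows).encode("ascii"), dtype="S1"
    ).reshape(fam.n_sequences, fam.length)
    n = fam.n_sequences
    values = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i] != arr[i + 1:]).mean(axis=1)
        values[i, i + 1:] = diff
        values[i + 1:, i] = diff
    return DistanceMatrix(fam.labels, values, "embedding")


def sequence_keyed_embeddings(
    fam: AlignedFamily, cfg: SyntheticConfig
) -> tuple[RepresentationSet, NeuronSet]:
    """Plant embeddings keyed to sequence content (via Hamming distances).

    Because the keying distance depends on residue order, regenerating the
    embeddings from shuffled sequences degrades their agreement with the
    tree — the mechanism behind the shuffle null.
    """
    return simulate_embeddings(hamming_matrix(fam), cfg)


def simulate_attention(
    m_lg: DistanceMatrix, cfg: SyntheticConfig
) -> AttentionHeadMatrix:
    """Attention whose symmetrized form has ESS of the configured sign.

    values = s * (m_lg + noise) + antisymmetric perturbation; the
    perturbation cancels exactly under A + A^T, so at zero noise the
    symmetrized matrix is an affine image of the patristic matrix with
    Pearson ESS exactly +/-1.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_ATTENTION])
    n = m_lg.n
    sign = 1.0 if cfg.attention_sign == "positive" else -1.0
    scale = float(np.std(m_lg.condensed())) or 1.0
    noise = np.zeros((n, n))
    if cfg.noise_sigma > 0:
        iu = np.triu_indices(n, k=1)
        noise[iu] = rng.standard_normal(len(iu[0]))
        noise += noise.T
    raw = rng.standard_normal((n, n))
    antisym = 0.5 * (raw - raw.T) * 0.1 * scale
    values = sign * (m_lg.values + cfg.noise_sigma * scale * noise) + antisym
    layer, head = (1, 5) if sign > 0 else (3, 12)
    return AttentionHeadMatrix(m_lg.labels, layer, head, values)


def make_fixture_bundle(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write a complete synthetic dataset and return its manifest.

    The bundle holds the alignment (FASTA and Stockholm), the true tree plus
    jittered branch-length replicates, the averaged patristic matrix, planted
    and composition representation files, positive and negative attention
    heads, the planted-neuron record, and a JSON manifest of paths,
    parameters, and the seed.  Re-running with the same config reproduces
    every file byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tree = simulate_tree(cfg)
    fam = simulate_alignment(tree, cfg)
    write_alignment(fam, out_dir / "alignment.fasta", "fasta")
    write_alignment(fam, out_dir / "alignment.sto", "stockholm")

    (out_dir / "true_tree.nwk").write_text(tree.to_newick() + "\n")
    rng = np.random.default_rng([cfg.seed, _STREAM_JITTER])
    replicate_paths = []
    matrices = []
    for i in range(cfg.n_tree_replicates):
        rep = jitter_tree(tree, cfg.tree_jitter_sigma, rng)
        path = out_dir / f"tree_rep{i:02d}.nwk"
        path.write_text(rep.to_newick() + "\n")
        replicate_paths.append(path.name)
        matrices.append(patristic_matrix(rep, fam.labels))
    m_lg = average_matrices(matrices)
    m_lg.to_tsv(out_dir / "lg_matrix.tsv")

    embeddings, planted = simulate_embeddings(m_lg, cfg)
    composition = onehot_composition(degap(fam))
    save_representation_sets([embeddings, composition], out_dir / "representations")

    att_pos = simulate_attention(m_lg, cfg)
    neg_cfg = SyntheticConfig(**{**asdict(cfg), "attention_sign": "negative"})
    att_neg = simulate_attention(m_lg, neg_cfg)
    save_attention_heads([att_pos, att_neg], out_dir / "attention")

    (out_dir / "planted_neurons.json").write_text(
        json.dumps({"salient": list(planted.indices)}, sort_keys=True) + "\n"
    )

    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "gap_percentage": gap_percentage(fam),
        "paths": {
            "alignment_fasta": "alignment.fasta",
            "alignment_stockholm": "alignment.sto",
            "true_tree": "true_tree.nwk",
            "tree_replicates": replicate_paths,
            "lg_matrix": "lg_matrix.tsv",
            "representations": "representations",
            "attention": "attention",
            "planted_neurons": "planted_neurons.json",
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
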