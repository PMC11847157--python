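# Methods

## Reference distances from trees

The evolutionary reference for a family is its patristic distance matrix:
for each leaf pair, the sum of branch lengths along the connecting path.
Paths are resolved through parent pointers to the most recent common
ancestor and summed with compensated summation (`math.fsum`), so the result
is independent of traversal order.  Patristic distance is invariant to
rooting, so rooted and unrooted input trees are treated identically.  When
several replicate trees are supplied (e.g. inferences under different
random seeds), their matrices are averaged element-wise after reordering to
a common label order — averaging matrices, not trees, since replicates may
disagree on topology.  The canonical label order everywhere is the MSA row
order, which prevents silent misalignment between matrices built from
different sources.

## Representation spaces

Three spaces are compared against the reference:

* **Embeddings** — one D-vector per sequence, typically the mean over a
  model layer's per-residue vectors (`mean_pool`).  Distances are
  Euclidean.
* **Composition** — relative amino-acid frequencies per sequence.  Rows
  sum to 1 so composition is decoupled from length, and gaps are dropped
  from aligned input: composition is a property of the protein, not of the
  alignment.  This is the order-insensitive baseline.
* **Column attention** — an N×N inter-sequence attention matrix
  (length-averaged first if supplied per column), symmetrized as `A + Aᵀ`
  with no ½ factor; both ESS variants are invariant to that overall scale.

Representations are consumed from files (one `.npy` per (model, layer)
plus a JSON manifest mapping row index to sequence label); computing them
from model weights is out of scope.  Ambiguity codes B/Z/U/O are folded
into X, which is appended to the working alphabet; Stockholm `.` and `-`
are both gaps; parsing is case-insensitive.

## ESS

ESS correlates the strict upper triangles of two matrices — Spearman
(average ranks) and Pearson.  Diagonal and lower triangle are excluded:
the N guaranteed zeros and the duplicated entries would only inflate
agreement.  A zero-variance triangle yields an explicit `degenerate` flag
with NaN coefficients rather than a silent zero, so degenerate cases can
never leak into averages or win counts.  Win counts across datasets award
a win only for a strict maximum; ties are tallied separately.

## Distance scales and strata

Per reference sequence, three member groups probe different resolutions:
*broad* (m = 10 members at sorted-distance ranks `round(i·(N−2)/(m−1))`,
i = 0..m−1 — an even spacing that provably includes the nearest and
farthest member), *fine* (the 10 closest), and *all* (every other
sequence).  Distance ties are always broken by label order, so results are
platform-independent.  The per-dataset summary averages per-reference
correlations; a reference degenerate at any scale is dropped from all
three (and counted), keeping the scales commensurable.  "All" is read
per-reference (N−1 partners) for the same reason.  Group strata default to
pooled tertiles of group means and variances (left-closed intervals, last
interval closed) because three levels per axis are wanted but no canonical
thresholds exist.

## Shuffle null

Each sequence of length L undergoes `floor(0.8·L)` swap operations, each
exchanging two uniformly chosen distinct positions (one RNG draw per
swap).  This is the operation-count reading of "80% of sites" — the
alternative (swap until 80% of positions are touched) would make the
operation count stochastic.  Swaps preserve the per-row character multiset
exactly, so composition matrices are bit-identical under the null while
residue order is destroyed.  Aligned input is shuffled at aligned length,
gaps included.

## Neuron probe

Pairs (i, j) are sampled uniformly without replacement (9000 by default;
if the pair universe is smaller, every pair is used, with a warning).
Features are `|z_i − z_j|` over neurons whose activation variance
(denominator N) strictly exceeds the 20th percentile of per-neuron
variances.  An elastic net — squared error plus L1 and L2 penalties, i.e.
`(1/2K)Σ(l_v − l̂_v)² + λ₁‖θ‖₁ + λ₂‖θ‖₂²` — is fitted on a 70/30 split,
with the penalty mix chosen by 5-fold cross-validation on the training
split over mixing ratios {0.1, 0.5, 0.9} × strengths log-spaced 1e-4..1e1.
Features are standardized on the training split (penalty fairness across
neurons of different scales); the held-out R² is reported per run.

**Saliency scale.**  Each run reports coefficients on two scales: the
original feature scale (directly usable for prediction) and the
standardized scale.  Saliency sums absolute *standardized* coefficients
across runs.  This choice matters: back-transforming divides by the
feature's training standard deviation, so near-constant noise neurons
would inherit the largest original-scale coefficients and invert the
ranking — verified on planted data, where original-scale saliency places
zero planted neurons in the top bins while standardized saliency places
only planted neurons there and makes top-bin ablation beat bottom-bin
ablation in every seed.

**Binning.**  Neurons sorted by saliency descending (ties by index) are
binned under two schemes.  *Mass* (default): top-X% is the smallest prefix
holding X% of total saliency, bottom-25% the largest suffix holding at
most 25% — this matches a "neurons constituting X% of the weights"
definition and adapts to how concentrated the signal is.  *Count*: top-X%
is the first ⌈X%·D′⌉ neurons.  Top bins are nested under both schemes.
Note that when saliency is concentrated (as it is for planted
tree-metric signal, whose MDS coordinate scales decay with eigenvalue),
mass-based top bins are very small and should be read as "the neurons
that dominate the signal", not as a fixed fraction of neurons.

**Ablation.**  A bin is validated by recomputing the ESS from the masked
representation containing only that bin's neurons.  Keeping all neurons
reproduces the full-representation ESS exactly.

## Synthetic data

The generator provides ground truth for every pipeline stage:

* **Trees** — Yule (pure-birth) topologies; every branch length is an
  independent exponential with mean 1/birth_rate (default 0.5), giving
  pairwise distances spanning roughly 0.5–10, comparable to deep protein
  family trees.
* **Alignments** — root sequence uniform over 20 amino acids; per branch
  of length t, each site substitutes with probability 1 − exp(−r·t) to a
  uniform different residue (a symmetric 20-state process — a monotone
  distance–divergence relation is what the tests need, not a realistic
  exchangeability matrix); indels arise as a Poisson process per site with
  geometric lengths, insertions opening fresh columns and deletions
  writing gaps.  A bisection helper calibrates the indel rate to a target
  gap fraction (±2 percentage points), reaching both the low-gap (≤ 20%)
  and high-gap (≥ 70%) regimes.  Replicate trees are emulated by
  log-normal branch-length jitter (σ = 0.1) on the true tree.
* **Planted embeddings** — classical MDS coordinates of the (optionally
  sqrt- or log1p-distorted) patristic matrix, with negative eigenvalues
  clamped (tree metrics need not be Euclidean), written into a uniformly
  chosen salient neuron subset of size ⌈salient_fraction·D⌉; remaining
  neurons carry Gaussian noise scaled by noise_sigma times the median
  nonzero coordinate magnitude, and salient coordinates receive additive
  Gaussian jitter of scale noise_sigma.  Pairwise Euclidean distance is
  then a noisy monotone image of patristic distance with signal confined
  to a known neuron set.
* **Attention** — `s·(M_LG + noise) + antisymmetric perturbation` with
  s = ±1; the antisymmetric part cancels exactly under `A + Aᵀ`, so at
  zero noise the symmetrized matrix is an affine image of the reference
  with Pearson ESS exactly ±1.  The positive head is tagged (layer 1,
  head 5) and the negative head (layer 3, head 12), mirroring the
  empirically observed sign flip between early and late attention heads.
* **Sequence-keyed embeddings** — embeddings planted from the alignment's
  normalized Hamming matrix (order-sensitive), so regenerating them from
  shuffled sequences degrades tree agreement; this closes the loop for the
  shuffle null.

All generators draw from per-operation seeded streams and are
byte-reproducible given the config; fixture bundles re-written with the
same seed are byte-identical, which the end-to-end determinism test
asserts across the whole simulate → ess → lhs → probe pipeline.

What the generator does **not** emulate: site-rate heterogeneity, realistic
exchangeabilities (LG), domain architecture, alignment error, or the
geometry of any particular language model's embedding space.  Passing
tests therefore demonstrate that the *measurement machinery* is correct
and well-calibrated, not that any real model encodes phylogeny.

## Numerical choices and edge cases

Degenerate inputs (constant distance vectors, zero-variance targets,
all-zero saliency) raise or flag explicitly rather than returning NaN/0
silently.  Distance ties in neighbour selection and sampling break by
label order; saliency ties break by neuron index.  Percentiles use linear
interpolation.  The broad-sample index formula uses floor(x + 0.5)
rounding to avoid platform-dependent banker's rounding.  Alignments that
evolve an all-gap sequence are resampled (up to five times, with a
warning).

## Problem sizes

The test and acceptance workloads use N = 80 leaves / D = 256 neurons for
ESS-level checks (20–30 seeds), N = 150 / D = 512 with 10% salient
neurons, 3000 pairs and 3 probe repeats for probe recovery (5 seeds), and
N = 40 for alignment-level checks — sizes at which every quantity is
stable across seeds while the full suite runs in well under a minute of
compute per check.

## Known limitations

* The probe's mass-scheme top bins do not enumerate the full planted
  salient set when signal concentrates in a few dimensions (see Binning);
  bin precision and ablation contrasts are the meaningful recovery
  metrics in that regime, and both are reported.
* MDS planting is exact only for Euclidean-realizable metrics; for general
  tree metrics the clamped reconstruction bounds ESS slightly below 1
  even at zero noise.
* The gap-fraction calibration targets the realized alignment for the
  configured seed, not the expected value over seeds.
* Hypothesis tests comparing ESS distributions (Wilcoxon,
  Kolmogorov–Smirnov) are exposed only as thin wrappers around scipy.
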