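# phyloreps

Do vector representations of homologous protein sequences recapitulate the
distances a phylogenetic tree implies?  `phyloreps` answers this question
quantitatively.  It compares any per-sequence representation space — pooled
protein-language-model embeddings, amino-acid composition vectors, or
symmetrized column-attention matrices — against the patristic distance
matrix of one or more trees for the same family, and probes *where* in the
representation the evolutionary signal lives.

It is aimed at researchers studying what protein language models learn
about evolution, and ships a synthetic benchmark (trees, indel-bearing
alignments, planted embedding spaces) so the whole pipeline runs and is
tested without any external data or model inference.

## The quantities it computes

**ESS (Evolutionary Similarity Score).**  For a family with patristic
matrix `M_LG` (averaged element-wise over replicate trees) and a
representation-space distance matrix `M_rep` (Euclidean between
per-sequence vectors, or symmetrized attention `A + Aᵀ`), the ESS is the
correlation over the strict upper triangles:

    ESS_ρ = ρ(upper(M_rep), upper(M_LG))      (Spearman, average ranks)
    ESS_r = r(upper(M_rep), upper(M_LG))      (Pearson)

**Scale-resolved ESS.**  For every reference sequence, per-reference
correlations over its *broad* group (10 members evenly spaced over sorted
patristic distance), its *fine* group (the 10 closest), and *all* other
sequences, averaged per dataset.  Groups can be stratified by mean and
variance of member distance (close/intermediate/remote ×
not/moderately/highly divergent) to isolate recurring tree motifs.

**LHS (local homolog similarity).**  Jaccard overlap `|K_LG ∩ K_rep| /
|K_LG ∪ K_rep|` between the K nearest neighbours of a reference in tree
space and in representation space, binned into disagree (0), low (0, 0.5],
high (0.5, 1), agree (= 1).

**Shuffle null.**  Chance-level control: each sequence undergoes
`floor(0.8·L)` random position swaps, preserving composition exactly while
destroying order.

**Neuron saliency probe.**  An elastic net predicts patristic distance from
`|z_i − z_j|` features over variance-filtered neurons (9000 sampled pairs,
70/30 split, penalties chosen by cross-validation, 10 repeats).  Neuron
saliency is the summed absolute standardized coefficient across repeats;
neurons are binned (top 10/25/50/75%, bottom 25%, by saliency mass or
count) and each bin is validated by *ablation*: the ESS recomputed from
that bin's neurons alone.

## Worked example

```python
from phyloreps import (
    SyntheticConfig, simulate_tree, simulate_alignment, simulate_embeddings,
    patristic_matrix, pairwise_euclidean, ess, dataset_scale_summary,
    lhs_table, gap_percentage,
)

cfg = SyntheticConfig(seed=1)            # 80 leaves, 256 neurons, 10% salient
tree = simulate_tree(cfg)
fam = simulate_alignment(tree, cfg)
m_lg = patristic_matrix(tree, fam.labels)
emb, planted = simulate_embeddings(m_lg, cfg)

print(f"N={fam.n_sequences}  L={fam.length}  gap={gap_percentage(fam):.3f}")
res = ess(m_lg, pairwise_euclidean(emb))
print(f"ESS_rho={res.rho:.4f}  ESS_r={res.r:.4f}  pairs={res.n_pairs}")
print(dataset_scale_summary(m_lg, pairwise_euclidean(emb)))
print(lhs_table(m_lg, [emb], Ks=(10,)).to_string(index=False))
```

prints

```
N=80  L=176  gap=0.144
ESS_rho=0.9807  ESS_r=0.9808  pairs=3160
{'broad': 0.9862, 'fine': 0.884, 'all': 0.9815, 'n_references': 80, 'n_excluded': 0}
representation  K  pct_disagree  pct_low  pct_high  pct_agree  n_references
planted:output 10           0.0     1.25      80.0      18.75            80
```

The planted embedding reproduces the tree's distance structure almost
perfectly at the full-matrix scale (ESS ≈ 0.98), best at the broad scale
and worst at the fine scale (0.986 vs 0.884) — close neighbours are the
hardest to order under noise — and its 10-nearest-neighbour sets overlap
highly (but rarely perfectly) with the tree's.

The same analyses run from the shell on files (FASTA/Stockholm alignments,
Newick trees, `.npy` arrays with a JSON label manifest):

```bash
phyloreps simulate --seed 1 --out-dir bundle/
phyloreps ess --alignment bundle/alignment.fasta \
    --tree bundle/tree_rep00.nwk --tree bundle/tree_rep01.nwk \
    --representations bundle/representations --attention bundle/attention \
    --out ess.tsv
phyloreps lhs ...   # and: scales, probe, pipeline
```

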