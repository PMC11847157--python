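"""End-to-end driver: fixture bundle -> ESS / scales / LHS / probe outputs.

Used both by the command-line interface and by reproducibility checks; every
output file is a deterministic function of the synthetic config (seed
included), with no timestamps or machine-specific content.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .family_io import (
    DistanceMatrix,
    classify_gap_category,
    read_alignment,
)
from .local_homology import lhs_table
from .neuron_probe import ProbeConfig, evolution_probe
from .representation_spaces import (
    load_attention_heads,
    load_representation_sets,
    pairwise_euclidean,
    symmetrize_column_attention,
)
from .rsa_ess import dataset_scale_summary, ess
from .synthetic_data import SyntheticConfig, make_fixture_bundle

_FLOAT_FMT = "%.10g"


def ess_table(
    m_lg: DistanceMatrix, rep_sets, attention_heads, dataset: str, gap_category: str
) -> pd.DataFrame:
    """One ESS row per representation (embeddings and symmetrized attention)."""
    rows = []
    for rep in rep_sets:
        res = ess(m_lg, pairwise_euclidean(rep), context=dataset)
        rows.append(
            {
                "dataset": dataset,
                "model_tag": rep.model_tag,
                "layer_tag": rep.layer_tag,
                "rho": res.rho,
                "r": res.r,
                "n_pairs": res.n_pairs,
                "gap_category": gap_category,
            }
        )
    for att in attention_heads:
        res = ess(m_lg, symmetrize_column_attention(att), context=dataset)
        rows.append(
            {
                "dataset": dataset,
                "model_tag": "attention",
                "layer_tag": f"L{att.layer}H{att.head}",
                "rho": res.rho,
                "r": res.r,
                "n_pairs": res.n_pairs,
                "gap_category": gap_category,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    cfg: SyntheticConfig,
    out_dir: str | Path,
    probe_cfg: ProbeConfig | None = None,
) -> dict:
    """Simulate a bundle, then compute ESS, scale summary, LHS, and probe.

    Returns a dict of output paths; all outputs are byte-reproducible given
    the same configs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle_dir = out_dir / "bundle"
    make_fixture_bundle(cfg, bundle_dir)

    fam = read_alignment(bundle_dir / "alignment.fasta", "fasta")
    m_lg = DistanceMatrix.from_tsv(bundle_dir / "lg_matrix.tsv", "patristic")
    reps = load_representation_sets(bundle_dir / "representations")
    atts = load_attention_heads(bundle_dir / "attention")
    gap_category = classify_gap_category(fam, enforce_size=False)
    dataset = fam.family_id

    table = ess_table(m_lg, reps, atts, dataset, gap_category)
    table.to_csv(out_dir / "ess.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    planted = next(r for r in reps if r.model_tag == "planted")
    summary = dataset_scale_summary(m_lg, pairwise_euclidean(planted))
    pd.DataFrame([{"dataset": dataset, **summary}]).to_csv(
        out_dir / "scales.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    Ks = tuple(k for k in (5, 10, 20) if k <= m_lg.n - 1)
    lhs_df = lhs_table(m_lg, reps, Ks)
    lhs_df.to_csv(out_dir / "lhs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    probe_cfg = probe_cfg or ProbeConfig(seed=cfg.seed)
    probe = evolution_probe(planted, m_lg, probe_cfg)
    (out_dir / "probe.json").write_text(
        json.dumps(probe.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    saliency_df = pd.DataFrame(
        {
            "neuron": list(probe.kept_neurons.indices),
            "saliency": list(probe.saliency),
        }
    ).sort_values("saliency", ascending=False, kind="stable")
    saliency_df.to_csv(
        out_dir / "saliency.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    run_log = {
        "synthetic_config": asdict(cfg),
        "probe_config": {
            "n_pairs": probe_cfg.n_pairs,
            "train_fraction": probe_cfg.train_fraction,
            "n_runs": probe_cfg.n_runs,
            "variance_percentile": probe_cfg.variance_percentile,
            "l1_ratios": list(probe_cfg.l1_ratios),
            "alphas": list(probe_cfg.alphas),
            "cv_folds": probe_cfg.cv_folds,
            "seed": probe_cfg.seed,
            "bin_scheme": probe_cfg.bin_scheme,
        },
    }
    (out_dir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n"
    )
    return {
        "bundle": str(bundle_dir),
        "ess": str(out_dir / "ess.tsv"),
        "scales": str(out_dir / "scales.tsv"),
        "lhs": str(out_dir / "lhs.tsv"),
        "probe": str(out_dir / "probe.json"),
        "saliency": str(out_dir / "saliency.tsv"),
        "run_log": str(out_dir / "run_log.json"),
    }
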