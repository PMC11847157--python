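import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phyloreps import (
    AlignedFamily,
    DistanceMatrix,
    broad_sample,
    dataset_scale_summary,
    ess,
    fine_sample,
    group_correlation,
    shuffle_stimulus,
    stratify_groups,
    win_counts,
)
from phyloreps.family_io import LabelError
from phyloreps.rsa_ess import GroupSample, all_sample
from .conftest import random_symmetric_matrix


class TestESS:
    def test_self_similarity(self, chain_matrix):
        res = ess(chain_matrix, chain_matrix)
        assert res.rho == 1.0 and res.r == pytest.approx(1.0, abs=1e-12)
        assert res.n_pairs == 6

    def test_monotone_nonlinear_transform(self, chain_matrix):
        warped = DistanceMatrix(
            chain_matrix.labels, np.expm1(chain_matrix.values), "embedding"
        )
        res = ess(chain_matrix, warped)
        assert res.rho == 1.0
        assert res.r < 1.0

    def test_matches_from_definition_oracle(self):
        rng = np.random.default_rng(12)
        a = random_symmetric_matrix(6, rng)
        b = random_symmetric_matrix(6, rng)
        res = ess(a, b)
        x, y = a.condensed(), b.condensed()
        rho_oracle = float(
            np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        )
        r_oracle = float(
            np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        )
        assert res.rho == pytest.approx(rho_oracle, abs=1e-12)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)

    def test_degenerate_triangle_flagged(self, chain_matrix):
        const = DistanceMatrix(
            chain_matrix.labels,
            np.ones((4, 4)) - np.eye(4),
            "embedding",
        )
        res = ess(chain_matrix, const)
        assert res.degenerate
        assert math.isnan(res.rho) and math.isnan(res.r)

    def test_invariant_under_common_relabelling(self, chain_matrix):
        rng = np.random.default_rng(13)
        other = random_symmetric_matrix(4, rng)
        other = DistanceMatrix(chain_matrix.labels, other.values, "embedding")
        base = ess(chain_matrix, other)
        perm = ("D", "B", "A", "C")
        res = ess(chain_matrix.reorder(perm), other.reorder(perm))
        assert res.rho == pytest.approx(base.rho, abs=1e-12)
        assert res.r == pytest.approx(base.r, abs=1e-12)

    def test_label_mismatch_raises(self, chain_matrix):
        rng = np.random.default_rng(14)
        with pytest.raises(LabelError):
            ess(chain_matrix, random_symmetric_matrix(4, rng))


class TestShuffleStimulus:
    def test_preserves_per_row_composition(self, toy_family):
        shuffled = shuffle_stimulus(toy_family, 0.8, seed=5)
        for before, after in zip(toy_family.rows, shuffled.rows):
            assert Counter(before) == Counter(after)
            assert len(before) == len(after)

    def test_swap_count_and_stream_consumption(self):
        # Re-derive the expected output: floor(0.8 * 10) = 8 swaps per row,
        # one two-position draw each, rows processed in order.
        fam = AlignedFamily("f", ("A", "B"), ("ACDEFGHIKL", "MNPQRSTVWY"))
        result = shuffle_stimulus(fam, 0.8, seed=42)
        rng = np.random.default_rng(42)
        expected = []
        for row in fam.rows:
            chars = list(row)
            for _ in range(8):
                i, j = rng.choice(10, size=2, replace=False)
                chars[i], chars[j] = chars[j], chars[i]
            expected.append("".join(chars))
        assert result.rows == tuple(expected)

    def test_deterministic_given_seed(self, toy_family):
        a = shuffle_stimulus(toy_family, 0.8, seed=3)
        b = shuffle_stimulus(toy_family, 0.8, seed=3)
        assert a.rows == b.rows
        assert a.rows != shuffle_stimulus(toy_family, 0.8, seed=4).rows

    def test_short_sequence_rejected(self):
        fam = AlignedFamily("f", ("A",), ("C",))
        with pytest.raises(ValueError):
            shuffle_stimulus(fam, 0.8, seed=0)


def distinct_distance_matrix(n: int) -> DistanceMatrix:
    """Distances from a line of points with strictly distinct gaps."""
    pos = np.cumsum(np.linspace(1.0, 2.0, n))
    values = np.abs(np.subtract.outer(pos, pos))
    return DistanceMatrix(tuple(f"s{i:02d}" for i in range(n)), values, "patristic")


class TestScaleSampling:
    def test_broad_exhaustive_when_m_equals_pool(self):
        m = distinct_distance_matrix(11)
        g = broad_sample(m, "s00", m=10)
        assert set(g.members) == set(m.labels) - {"s00"}

    def test_broad_even_spacing_ranks(self):
        m = distinct_distance_matrix(20)
        g = broad_sample(m, "s00", m=10)
        ordered = sorted(
            (label for label in m.labels if label != "s00"),
            key=lambda l: m.values[0, m.index_of(l)],
        )
        picked_ranks = sorted(ordered.index(l) for l in g.members)
        assert picked_ranks == [0, 2, 4, 6, 8, 10, 12, 14, 16, 18]

    def test_broad_contains_nearest_and_farthest(self, medium_tree_and_matrix):
        _, _, m = medium_tree_and_matrix
        ref = m.labels[0]
        g = broad_sample(m, ref)
        dists = [m.values[0, m.index_of(l)] for l in m.labels[1:]]
        assert min(dists) == m.values[0, m.index_of(g.members[0])]
        assert max(dists) == m.values[0, m.index_of(g.members[-1])]

    def test_fine_on_chain(self, chain_matrix):
        g = fine_sample(chain_matrix, "A", m=2)
        assert set(g.members) == {"B", "C"}

    def test_fine_matches_full_sort(self, medium_tree_and_matrix):
        _, _, m = medium_tree_and_matrix
        ref = m.labels[3]
        g = fine_sample(m, ref)
        i = m.index_of(ref)
        oracle = sorted(
            (l for l in m.labels if l != ref),
            key=lambda l: (m.values[i, m.index_of(l)], l),
        )[:10]
        assert set(g.members) == set(oracle)

    def test_too_few_sequences(self, chain_matrix):
        with pytest.raises(ValueError):
            broad_sample(chain_matrix, "A", m=10)


class TestGroupCorrelation:
    def test_linear_map_gives_unit_correlation(self, medium_tree_and_matrix):
        _, _, m = medium_tree_and_matrix
        doubled = DistanceMatrix(m.labels, 2 * m.values, "embedding")
        g = fine_sample(m, m.labels[0])
        assert group_correlation(m, doubled, g) == pytest.approx(1.0, abs=1e-12)

    def test_equal_distances_degenerate(self):
        values = np.ones((5, 5)) - np.eye(5)
        m = DistanceMatrix(tuple("abcde"), values, "patristic")
        g = GroupSample("a", ("b", "c", "d"), "fine", 1.0, 0.0)
        assert math.isnan(group_correlation(m, m, g))


class TestDatasetScaleSummary:
    def test_identity_representation_scores_one_everywhere(self, medium_tree_and_matrix):
        _, _, m = medium_tree_and_matrix
        copy = DistanceMatrix(m.labels, m.values.copy(), "embedding")
        s = dataset_scale_summary(m, copy)
        for key in ("broad", "fine", "all"):
            assert s[key] == pytest.approx(1.0, abs=1e-9)
        assert s["n_excluded"] == 0

    def test_minimum_size_enforced(self):
        m = distinct_distance_matrix(11)
        with pytest.raises(ValueError):
            dataset_scale_summary(m, m)


class TestStratifyGroups:
    def test_named_bins(self):
        groups = [
            GroupSample("r", ("a", "b", "c"), "broad", mean, var)
            for mean, var in [(0.1, 0.0), (1.0, 0.5), (5.0, 3.0)]
        ]
        labelled = stratify_groups(groups)
        assert [s.mean_bin for _, s in labelled] == [
            "close", "intermediate", "remote",
        ]
        assert [s.var_bin for _, s in labelled] == [
            "not_divergent", "moderately_divergent", "highly_divergent",
        ]

    def test_identical_groups_share_a_stratum(self):
        groups = [GroupSample("r", ("a", "b", "c"), "fine", 1.0, 0.2)] * 5
        strata = {s for _, s in stratify_groups(groups)}
        assert len(strata) == 1

    def test_bin_counts_match_histogram_oracle(self):
        rng = np.random.default_rng(15)
        groups = [
            GroupSample("r", ("a", "b", "c"), "broad",
                        float(m), float(v))
            for m, v in zip(rng.uniform(0, 10, 300), rng.uniform(0, 4, 300))
        ]
        labelled = stratify_groups(groups)
        means = np.array([g.mean_dist for g in groups])
        edges = np.quantile(means, [1 / 3, 2 / 3])
        oracle = Counter(
            int(np.searchsorted(edges, v, side="right")) for v in means
        )
        got = Counter(s.mean_bin for _, s in labelled)
        assert got["close"] == oracle[0]
        assert got["intermediate"] == oracle[1]
        assert got["remote"] == oracle[2]

    def test_decreasing_edges_rejected(self):
        g = [GroupSample("r", ("a", "b", "c"), "fine", 1.0, 0.2)]
        with pytest.raises(ValueError):
            stratify_groups(g, mean_edges=(2.0, 1.0))


class TestWinCounts:
    def test_dominating_representation_takes_all(self):
        df = pd.DataFrame(
            [
                {"dataset": d, "representation": rep, "rho": v, "r": v}
                for d in ("d1", "d2")
                for rep, v in (("big", 0.9), ("small", 0.1))
            ]
        )
        out = win_counts(df)
        assert out["rho"]["wins"] == {"big": 2, "small": 0}
        assert out["r"]["ties"] == 0

    def test_ties_award_no_win(self):
        df = pd.DataFrame(
            [
                {"dataset": "d1", "representation": "a", "rho": 0.5, "r": 0.5},
                {"dataset": "d1", "representation": "b", "rho": 0.5, "r": 0.4},
            ]
        )
        out = win_counts(df)
        assert out["rho"]["ties"] == 1
        assert sum(out["rho"]["wins"].values()) == 0
        assert out["r"]["wins"]["a"] == 1

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(16)
        rows = []
        for d in range(12):
            for rep in ("x", "y", "z"):
                rows.append(
                    {
                        "dataset": f"d{d}",
                        "representation": rep,
                        "rho": rng.uniform(),
                        "r": rng.uniform(),
                    }
                )
        df = pd.DataFrame(rows)
        out = win_counts(df)
        for metric in ("rho", "r"):
            oracle = Counter(
                sub.loc[sub[metric].idxmax(), "representation"]
                for _, sub in df.groupby("dataset")
            )
            assert out[metric]["wins"] == {
                rep: oracle.get(rep, 0) for rep in ("x", "y", "z")
            }


class TestScaleOrderingUnderNoise:
    def test_all_sample_covers_everyone(self, medium_tree_and_matrix):
        _, _, m = medium_tree_and_matrix
        g = all_sample(m, m.labels[0])
        assert len(g.members) == m.n - 1

    def test_broad_beats_fine_under_multiplicative_noise(self, medium_tree_and_matrix):
        from phyloreps import multiplicative_noise_matrix

        _, _, m = medium_tree_and_matrix
        wins = 0
        for seed in range(10):
            noisy = multiplicative_noise_matrix(m, 0.3, seed)
            s = dataset_scale_summary(m, noisy)
            wins += s["broad"] >= s["fine"]
        assert wins >= 9
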