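"""Thresholding and weighted-topology metrics against brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aecnet.bands import BandSpec
from aecnet.connectivity import ConnectivityMatrix
from aecnet.graph_metrics import (
    MedianThresholder,
    apply_threshold,
    measures_from_matrices,
    pooled_median_threshold,
    weighted_global_efficiency,
    weighted_transitivity,
)

BAND = BandSpec("alpha", 8.0, 12.0)


def adjacency(entries, n):
    w = np.zeros((n, n))
    for i, j, v in entries:
        w[i, j] = w[j, i] = v
    return w


def matrix(w, subject="s", condition="Pre"):
    return ConnectivityMatrix(np.asarray(w, float), BAND, subject, condition)


# -- independent oracles ----------------------------------------------------


def transitivity_oracle(w):
    """Exhaustive ordered-triple enumeration of T."""
    n = w.shape[0]
    num = 0.0
    den = 0.0
    for i in range(n):
        k = int(np.sum(w[i] > 0))
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) == 3:
                    num += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
    return num / den if den else 0.0


def efficiency_oracle(w):
    """Floyd-Warshall all-pairs shortest paths on lengths 1/w."""
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum() / (n * (n - 1))


def random_graph(rng, n):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(iu[0].size) < rng.uniform(0.2, 0.9)
    vals = rng.uniform(0.01, 1.0, size=iu[0].size) * mask
    w[iu] = vals
    return w + w.T


# -- thresholding ------------------------------------------------------------


class TestThreshold:
    def test_pooled_median_midpoint(self):
        mats = [
            matrix(adjacency([(0, 1, 0.1), (0, 2, 0.2), (1, 2, 0.3)], 3)),
            matrix(adjacency([(0, 1, 0.4), (0, 2, 0.4), (1, 2, 0.4)], 3)),
        ]
        # pooled entries {0.1,0.2,0.3,0.4,0.4,0.4}: midpoint median 0.35
        assert pooled_median_threshold(mats) == pytest.approx(0.35)

    def test_four_value_pool_midpoint_rule(self):
        """Pool {0.1, 0.2, 0.3, 0.4} has midpoint median 0.25."""
        mats = [
            matrix(adjacency([(0, 1, v)], 2)) for v in (0.1, 0.2, 0.3, 0.4)
        ]
        assert pooled_median_threshold(mats) == pytest.approx(0.25)

    def test_singleton_and_duplication_invariance(self):
        m = matrix(adjacency([(0, 1, 0.5)], 2))
        assert pooled_median_threshold([m]) == pytest.approx(0.5)
        assert pooled_median_threshold([m, m]) == pytest.approx(0.5)

    def test_apply_threshold_boundary_keeps(self):
        m = matrix(adjacency([(0, 1, 0.1), (1, 2, 0.3), (0, 2, 0.25)], 3))
        thr = apply_threshold(m, 0.25)
        assert thr.weights[0, 1] == 0.0
        assert thr.weights[1, 2] == 0.3
        assert thr.weights[0, 2] == 0.25  # exactly at cutoff: retained

    def test_minus_inf_cutoff_is_identity(self):
        m = matrix(adjacency([(0, 1, -0.2), (1, 2, 0.3)], 3))
        np.testing.assert_array_equal(apply_threshold(m, -np.inf).weights, m.weights)

    def test_nonnegative_cutoff_removes_negative_entries(self):
        m = matrix(adjacency([(0, 1, -0.2), (1, 2, 0.3)], 3))
        assert apply_threshold(m, 0.0).weights[0, 1] == 0.0

    def test_thresholder_learns_cutoff_and_excludes_conditions(self):
        mats = [
            matrix(adjacency([(0, 1, 0.2)], 2), condition="Pre"),
            matrix(adjacency([(0, 1, 0.8)], 2), condition="Stim01"),
        ]
        assert MedianThresholder().fit(mats).cutoff_ == pytest.approx(0.5)
        thr = MedianThresholder(exclude_conditions=("Pre",)).fit(mats)
        assert thr.cutoff_ == pytest.approx(0.8)


# -- metrics ----------------------------------------------------------------


class TestTransitivity:
    def test_unit_clique(self):
        w = np.ones((5, 5)) - np.eye(5)
        assert weighted_transitivity(w) == pytest.approx(1.0)

    def test_hand_triangle(self):
        w = adjacency([(0, 1, 0.8), (0, 2, 0.5), (1, 2, 0.2)], 3)
        assert weighted_transitivity(w) == pytest.approx(0.08 ** (1 / 3), abs=1e-9)
        assert weighted_transitivity(w) == pytest.approx(0.430887, abs=1e-6)

    def test_star_graph_no_triangles(self):
        w = adjacency([(0, 1, 0.9), (0, 2, 0.9), (0, 3, 0.9)], 4)
        assert weighted_transitivity(w) == 0.0

    def test_degenerate_graph(self):
        assert weighted_transitivity(np.zeros((3, 3))) == 0.0

    def test_negative_weights_rejected(self):
        w = adjacency([(0, 1, -0.5)], 2)
        with pytest.raises(ValueError, match="negative"):
            weighted_transitivity(w)

    @given(st.integers(0, 10_000), st.floats(0.1, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_scales_linearly_in_weights(self, seed, c):
        w = random_graph(np.random.default_rng(seed), 8)
        base = weighted_transitivity(w)
        assert weighted_transitivity(np.clip(c, 0, None) * w) == pytest.approx(
            c * base, rel=1e-9, abs=1e-12
        )


class TestEfficiency:
    def test_two_node_graph(self):
        assert weighted_global_efficiency(adjacency([(0, 1, 0.7)], 2)) == pytest.approx(0.7)

    def test_hand_path_graph(self):
        w = adjacency([(0, 1, 0.5), (1, 2, 0.5)], 3)
        assert weighted_global_efficiency(w) == pytest.approx(5.0 / 12.0, abs=1e-9)

    def test_empty_graph(self):
        assert weighted_global_efficiency(np.zeros((4, 4))) == 0.0

    def test_single_node(self):
        assert weighted_global_efficiency(np.zeros((1, 1))) == 0.0

    def test_neglog_length_map(self):
        w = adjacency([(0, 1, 0.5)], 2)
        assert weighted_global_efficiency(w, length_map="neglog") == pytest.approx(
            1.0 / -np.log(0.5)
        )

    def test_adding_edge_never_decreases(self, rng):
        for _ in range(20):
            w = random_graph(rng, 7)
            e = weighted_global_efficiency(w)
            zeros = np.argwhere(np.triu(w == 0, k=1))
            if zeros.size == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.uniform(0.1, 1.0)
            assert weighted_global_efficiency(w2) >= e - 1e-12


class TestOracleAgreement:
    def test_random_graphs_match_bruteforce(self):
        """T and E agree with exhaustive enumeration to 1e-10."""
        rng = np.random.default_rng(1234)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            w = random_graph(rng, n)
            assert weighted_transitivity(w) == pytest.approx(
                transitivity_oracle(w), abs=1e-10
            )
            assert weighted_global_efficiency(w) == pytest.approx(
                efficiency_oracle(w), abs=1e-10
            )

    def test_permutation_invariance(self, rng):
        w = random_graph(rng, 9)
        perm = rng.permutation(9)
        wp = w[np.ix_(perm, perm)]
        assert weighted_transitivity(wp) == pytest.approx(
            weighted_transitivity(w), abs=1e-12
        )
        assert weighted_global_efficiency(wp) == pytest.approx(
            weighted_global_efficiency(w), abs=1e-12
        )


class TestMeasureTable:
    def test_long_format_and_thresholding(self, rng):
        mats = []
        for s in range(3):
            for cond in ("Pre", "Stim01"):
                mats.append(matrix(random_graph(rng, 6), subject=f"s{s}", condition=cond))
        table = measures_from_matrices(mats)
        assert list(table.columns) == ["subject", "condition", "band", "measure", "value"]
        assert len(table) == 2 * len(mats)
        assert set(table["measure"]) == {"T", "E"}
        assert (table["value"] >= 0).all()
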