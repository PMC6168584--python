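import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from deltanet.io import extract_pairs
from deltanet.network import (
    InsufficientOverlapError,
    UntestableError,
    bh_adjust,
    build_network,
    correlate_all,
    delta_matrix,
    neighborhood,
    sensitivity_compare,
    spearman_pair,
)
from deltanet.synthetic import block_design, generate_cohort


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestSpearmanPair:
    def test_strictly_monotone_gives_rho_one_p_zero(self):
        x = np.array([1.0, 2, 3, 5, 9])
        rho, p, n = spearman_pair(x, np.exp(x))
        assert rho == 1.0 and p == 0.0 and n == 5

    def test_hand_ranked_example(self):
        # ranks of y are (2,1,4,3,5): sum d^2 = 4, rho = 1 - 6*4/(5*24) = 0.8
        rho, _, _ = spearman_pair([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_is_untestable(self):
        with pytest.raises(UntestableError, match="rank variance"):
            spearman_pair([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_too_few_complete_pairs_is_untestable(self):
        x = [1.0, np.nan, 3.0, np.nan]
        with pytest.raises(UntestableError):
            spearman_pair(x, [1.0, 2.0, np.nan, 4.0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        rho, p, _ = spearman_pair(x, y)
        oracle_rho, oracle_p = stats.pearsonr(
            stats.rankdata(x, method="average"), stats.rankdata(y, method="average")
        )
        assert abs(rho - oracle_rho) < 1e-12
        # symmetry and invariance under strictly monotone transforms
        assert spearman_pair(y, x)[0] == pytest.approx(rho, abs=1e-12)
        assert spearman_pair(np.exp(x), y)[0] == pytest.approx(rho, abs=1e-12)


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 40)))
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestCorrelateAll:
    def test_three_biomarkers_give_three_entries(self):
        rng = np.random.default_rng(0)
        deltas = pd.DataFrame(rng.normal(size=(30, 3)), columns=["A", "B", "C"])
        entries = correlate_all(deltas)
        assert len(entries) == 3

    def test_pair_below_min_n_shrinks_family_to_nine(self):
        rng = np.random.default_rng(1)
        deltas = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("ABCDE"))
        # D and E share only 5 participants
        deltas.loc[:19, "D"] = np.nan
        deltas.loc[25:, "E"] = np.nan
        entries = correlate_all(deltas, min_n=10)
        assert len(entries) == 9
        keys = set(map(tuple, entries[["biomarker_a", "biomarker_b"]].to_numpy()))
        assert ("D", "E") not in keys

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(2)
        deltas = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("ABCD"))
        a = correlate_all(deltas)
        b = correlate_all(deltas[["D", "B", "A", "C"]])
        pd.testing.assert_frame_equal(a, b)


def _entries(rows):
    df = pd.DataFrame(rows, columns=["biomarker_a", "biomarker_b", "rho", "n", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


class TestNetwork:
    def test_no_significant_entries_gives_edgeless_network_with_nodes(self):
        net = build_network(_entries([("A", "B", 0.1, 50, 0.9), ("A", "C", 0.0, 50, 1.0)]))
        assert net.nodes == ["A", "B", "C"]
        assert net.edges.empty

    def test_significant_entry_becomes_signed_edge(self):
        net = build_network(_entries([("A", "B", -0.4, 80, 0.0001)]))
        assert len(net.edges) == 1
        g = net.to_networkx()
        assert g["A"]["B"]["weight"] == pytest.approx(-0.4)

    def test_neighborhood_is_a_star(self):
        net = build_network(
            _entries(
                [
                    ("A", "B", 0.5, 50, 1e-5),
                    ("A", "C", 0.4, 50, 1e-4),
                    ("A", "D", 0.4, 50, 1e-4),
                    ("B", "C", 0.6, 50, 1e-6),
                    ("D", "E", 0.1, 50, 0.9),
                ]
            )
        )
        star = neighborhood(net, "A")
        assert star.nodes == ["A", "B", "C", "D"]
        assert len(star.edges) == 3
        assert set(star.edges["biomarker_a"]) == {"A"}

    def test_isolated_focus_gives_single_node(self):
        net = build_network(_entries([("A", "B", 0.5, 50, 1e-5), ("A", "C", 0.1, 50, 0.9)]))
        star = neighborhood(net, "C")
        assert star.nodes == ["C"] and star.edges.empty

    def test_unknown_focus_raises(self):
        net = build_network(_entries([("A", "B", 0.5, 50, 1e-5)]))
        with pytest.raises(KeyError):
            neighborhood(net, "ZZZ")

    def test_planted_blocks_give_within_but_not_between_edges(self):
        table, _, truth = generate_cohort(block_design(n_blocks=2, block_size=3, seed=11))
        entries = correlate_all(delta_matrix(extract_pairs(table, 30)))
        net = build_network(entries)
        labels = truth["block_labels"]
        for row in net.edges.itertuples(index=False):
            assert labels[row.biomarker_a] == labels[row.biomarker_b]
        within = sum(
            1 for r in entries.itertuples(index=False)
            if labels[r.biomarker_a] == labels[r.biomarker_b]
        )
        assert len(net.edges) == within


class TestSensitivity:
    def test_identical_tables_give_r_one(self):
        e = _entries([("A", "B", 0.5, 50, 1e-5), ("A", "C", -0.2, 50, 0.1),
                      ("B", "C", 0.3, 50, 0.01)])
        r, table = sensitivity_compare(e, e)
        assert r == pytest.approx(1.0)
        assert len(table) == 3

    def test_disjoint_tables_raise(self):
        a = _entries([("A", "B", 0.5, 50, 1e-5)])
        b = _entries([("C", "D", 0.5, 50, 1e-5)])
        with pytest.raises(InsufficientOverlapError):
            sensitivity_compare(a, b)

    def test_random_subsample_preserves_correlation_structure(self):
        table, _, _ = generate_cohort(
            block_design(n_blocks=8, block_size=5, r_within=0.5, n_participants=1000, seed=5)
        )
        deltas = delta_matrix(extract_pairs(table, 30))
        full = correlate_all(deltas)
        rng = np.random.default_rng(5)
        subset = deltas.sample(frac=0.7, random_state=int(rng.integers(2**31)))
        stratum = correlate_all(subset)
        r, _ = sensitivity_compare(full, stratum)
        assert r > 0.9
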