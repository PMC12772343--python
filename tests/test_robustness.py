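import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from altigut import (
    compare_groups,
    games_howell,
    robustness_distribution,
    robustness_once,
    welch_anova,
)


def _oracle_surviving_fraction(G, removal):
    """Independent re-implementation: subgraph + drop isolates, via networkx."""
    H = G.subgraph(set(G.nodes) - set(removal)).copy()
    H.remove_nodes_from(list(nx.isolates(H)))
    return H.number_of_nodes() / G.number_of_nodes()


class TestRobustnessOnce:
    def test_complete_graph_is_half(self):
        K10 = nx.complete_graph(10)
        for seed in range(10):
            assert robustness_once(K10, 0.5, rng=seed) == 0.5

    def test_single_edge_collapses(self):
        G = nx.Graph([("u", "v")])
        assert robustness_once(G, 0.5, removal=["u"]) == 0.0

    def test_fraction_validated(self):
        with pytest.raises(ValueError):
            robustness_once(nx.complete_graph(4), 1.5)

    def test_matches_oracle_on_all_removals_of_small_graphs(self):
        """Exhaustive agreement with an independent networkx-based oracle
        on every removal set of several <= 12-node graphs."""
        graphs = [
            nx.star_graph(9),
            nx.path_graph(8),
            nx.gnp_random_graph(10, 0.3, seed=2),
            nx.gnp_random_graph(12, 0.25, seed=3),
        ]
        for G in graphs:
            G.remove_nodes_from(list(nx.isolates(G)))
            N = G.number_of_nodes()
            m = N // 2
            for removal in itertools.combinations(list(G.nodes), m):
                assert robustness_once(G, 0.5, removal=list(removal)) == pytest.approx(
                    _oracle_surviving_fraction(G, removal), abs=1e-12
                )

    def test_star_expectation_from_enumeration(self):
        """Mean over all C(10,5) removals of a 10-node star: the hub dies
        with probability 1/2, and with it every leaf."""
        star = nx.star_graph(9)
        vals = [robustness_once(star, 0.5, removal=list(r))
                for r in itertools.combinations(range(10), 5)]
        enumerated = np.mean(vals)
        assert enumerated == pytest.approx(0.25, abs=1e-12)
        res = robustness_distribution(star, 0.5, n_iter=400, seed=11)
        se = res.sd / np.sqrt(res.n_iterations)
        assert abs(res.mean - enumerated) <= 3 * se


class TestRobustnessDistribution:
    def test_complete_graph_all_half_zero_sd(self):
        res = robustness_distribution(nx.complete_graph(10), 0.5, n_iter=100, seed=0)
        assert (res.values == 0.5).all()
        assert res.sd == 0.0

    def test_deterministic_given_seed(self):
        G = nx.gnp_random_graph(40, 0.1, seed=5)
        a = robustness_distribution(G, 0.5, n_iter=50, seed=9)
        b = robustness_distribution(G, 0.5, n_iter=50, seed=9)
        assert (a.values == b.values).all()

    def test_monotone_in_removal_fraction(self):
        """Expected robustness never increases with the removed fraction."""
        G = nx.gnp_random_graph(40, 0.08, seed=6)
        G.remove_nodes_from(list(nx.isolates(G)))
        means = [robustness_distribution(G, f, n_iter=500, seed=13).mean
                 for f in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b - 0.01 for a, b in zip(means, means[1:]))

    def test_value_bounded_by_survivor_fraction(self):
        G = nx.gnp_random_graph(21, 0.15, seed=8)
        G.remove_nodes_from(list(nx.isolates(G)))
        res = robustness_distribution(G, 0.5, n_iter=200, seed=3)
        N = G.number_of_nodes()
        assert (res.values <= 0.5 + 1.0 / N + 1e-12).all()


class TestWelchAnova:
    def test_separated_groups(self, rng):
        groups = [rng.normal(0, 1, 20), rng.normal(100, 1, 20), rng.normal(200, 1, 20)]
        assert welch_anova(groups).p < 1e-10

    def test_two_groups_equals_squared_welch_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 2.5, 17)
        res = welch_anova([a, b])
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert res.F == pytest.approx(t**2, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        groups = {f"g{i}": rng.normal(i * 0.3, 1 + 0.3 * i, 10 + 3 * i) for i in range(4)}
        res = welch_anova(groups)
        df = pd.DataFrame([(k, v) for k, g in groups.items() for v in g],
                          columns=["g", "y"])
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.F == pytest.approx(ref["F"].iloc[0], rel=1e-9)
        assert res.p == pytest.approx(ref["p_unc"].iloc[0], rel=1e-9)
        assert res.df2 == pytest.approx(ref["ddof2"].iloc[0], rel=1e-9)

    def test_type_one_error_calibrated(self):
        """All groups from one distribution: rejection rate at alpha=0.05
        lands in (0.03, 0.07) over 1,000 simulations."""
        rng = np.random.default_rng(21)
        rejections = 0
        for _ in range(1000):
            groups = [rng.normal(0, 1, 15) for _ in range(4)]
            rejections += welch_anova(groups).p < 0.05
        assert 30 <= rejections <= 70

    def test_zero_variance_group_named(self):
        with pytest.raises(ValueError, match="flat"):
            welch_anova({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})


class TestGamesHowell:
    def test_k2_reduces_to_welch_t(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(0.6, 2, 11)
        gh = games_howell([a, b])
        _, p = stats.ttest_ind(a, b, equal_var=False)
        assert gh["p_adj_gh"].iloc[0] == pytest.approx(p, abs=1e-6)

    def test_identical_groups_near_one(self, rng):
        base = rng.normal(0, 1, 30)
        gh = games_howell([base, base + 1e-9 * rng.normal(size=30), base + 1e-9])
        assert (gh["p_adj_gh"] > 0.99).all()

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        groups = {f"g{i}": rng.normal(i * 0.5, 1 + 0.2 * i, 12 + 2 * i) for i in range(4)}
        gh = games_howell(groups)
        df = pd.DataFrame([(k, v) for k, g in groups.items() for v in g],
                          columns=["g", "y"])
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        np.testing.assert_allclose(np.sort(gh["p_adj_gh"]), np.sort(ref["pval"]),
                                   atol=1e-9)

    def test_shifted_mid_stratum_all_significant(self, rng):
        """Six strata of 100 replicates with the mid group shifted +3 sd:
        every comparison against the mid group comes out below 1e-4."""
        groups = {f"S{i}": rng.normal(0.35, 0.03, 100) for i in range(5)}
        groups["S2200_2600"] = rng.normal(0.35 + 3 * 0.03, 0.03, 100)
        result = compare_groups(groups)
        assert result.omnibus.p < 1e-10
        mid = result.pairwise[
            (result.pairwise["group_a"] == "S2200_2600")
            | (result.pairwise["group_b"] == "S2200_2600")
        ]
        assert len(mid) == 5
        assert (mid["p_adj_gh"] < 1e-4).all()
        assert len(result.pairwise) == 15
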