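import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altigut import (
    bh_adjust,
    fit_cubic,
    fit_linear,
    fit_piecewise,
    fit_spline_gcv,
    generate_piecewise_series,
    select_breakpoint_count,
    spearman_screen,
)


class TestLinear:
    def test_exact_line(self):
        x = np.linspace(0, 10, 30)
        fit = fit_linear(x, 2 * x)
        assert fit.coefficients[1] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.ones(10), np.arange(10))

    def test_null_pvalues_uniform(self):
        """Slope P under independence is uniform (KS at alpha 0.01)."""
        rng = np.random.default_rng(7)
        ps = [fit_linear(rng.normal(size=100), rng.normal(size=100)).p_value
              for _ in range(500)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_slope_recovery_small_noise(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 5, 200)
        fit = fit_linear(x, -x + rng.normal(0, 0.01, 200))
        assert -1.01 < fit.coefficients[1] < -0.99


class TestPiecewise:
    def test_noiseless_vertex_recovered_within_grid_step(self):
        x, y = generate_piecewise_series((2300.0,), (0.01, -0.01), 0.0, 0.0, 200, seed=3)
        fit = fit_piecewise(x, y, 1)
        assert abs(fit.breakpoints[0] - 2300.0) <= 16.0  # one grid step
        assert fit.r2 > 0.999

    def test_rss_never_worse_than_linear(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = np.sort(rng.uniform(0, 100, 60))
            y = rng.normal(size=60)
            assert fit_piecewise(x, y, 1).rss <= fit_linear(x, y).rss + 1e-9

    def test_two_breakpoints_recovered(self):
        x, y = generate_piecewise_series((2200.0, 3000.0), (0.01, -0.01, 0.01),
                                         1.0, 0.2, 200, seed=5)
        fit = fit_piecewise(x, y, 2)
        assert abs(fit.breakpoints[0] - 2200.0) <= 100
        assert abs(fit.breakpoints[1] - 3000.0) <= 100

    def test_null_f_test_rarely_significant(self):
        """On purely linear data the k=1 F-test stays above 0.05 in >= 90%."""
        rng = np.random.default_rng(19)
        sig = 0
        for _ in range(200):
            x = np.sort(rng.uniform(0, 10, 40))
            y = 0.5 * x + rng.normal(0, 1, 40)
            sig += fit_piecewise(x, y, 1).p_value < 0.05
        assert sig <= 20

    def test_rejects_bad_k(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError):
            fit_piecewise(x, x, 3)


class TestBreakpointSelection:
    @pytest.mark.parametrize(
        "breakpoints, slopes, noise, expected_k",
        [
            ((), (0.001,), 0.3, 0),
            ((2300.0,), (0.01, -0.01), 0.9, 1),  # noise 10% of signal range
            ((2300.0, 3000.0), (-0.0004, 0.0003, -0.00038), 0.03, 2),  # NDVI-like 3-phase
        ],
    )
    def test_simulated_shapes(self, breakpoints, slopes, noise, expected_k):
        hits = 0
        for rep in range(20):
            x, y = generate_piecewise_series(breakpoints, slopes, 0.8, noise,
                                             121, seed=300 + rep)
            hits += select_breakpoint_count(x, y) == expected_k
        assert hits >= 18


class TestSplineGCV:
    def test_sine_recovery(self):
        x = np.linspace(0, 2 * np.pi, 200)
        fit = fit_spline_gcv(x, np.sin(x))
        assert np.max(np.abs(fit.predict(x) - np.sin(x))) < 0.01

    def test_linear_data_selects_smallest_basis(self):
        rng = np.random.default_rng(1)
        small = 0
        edfs = []
        for _ in range(30):
            x = np.sort(rng.uniform(0, 1, 100))
            fit = fit_spline_gcv(x, 2 * x + rng.normal(0, 0.1, 100))
            small += len(fit.knots) == 3
            edfs.append(fit.edf)
        assert small >= 20
        assert np.mean(edfs) == pytest.approx(2.0, abs=0.5)

    def test_edf_bounded(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 1, 24))
        fit = fit_spline_gcv(x, rng.normal(size=24))
        assert fit.edf <= 12

    def test_hump_argmax_matches_peak(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(1400, 4400, 150))
        y = np.exp(-((x - 2400.0) ** 2) / (2 * 500.0**2)) + rng.normal(0, 0.05, 150)
        fit = fit_spline_gcv(x, y)
        assert abs(fit.argmax() - 2400.0) <= 200


class TestCubic:
    def test_exact_cubic(self):
        x = np.linspace(-2, 2, 40)
        fit = fit_cubic(x, x**3)
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.predict(x), x**3, atol=1e-8)

    def test_constant_y(self):
        fit = fit_cubic(np.arange(20.0), np.full(20, 3.0))
        assert fit.r2 == 0.0

    def test_hump_argmax_in_mid_range(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(1400, 4400, 100))
        y = -((x - 2500.0) / 1000.0) ** 2 + rng.normal(0, 0.05, 100)
        assert 2200 <= fit_cubic(x, y).argmax() <= 2800


class TestSpearmanScreen:
    def test_perfect_correlations(self, rng):
        alt = np.sort(rng.uniform(1400, 4400, 121))
        table = pd.DataFrame(
            {f"s{i}": [a, -a, 1.0] for i, a in enumerate(alt)},
            index=["up", "dn", "flat"],
        )
        res = spearman_screen(table, alt)
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["up", "p_raw"] < 1e-6
        assert res.loc["dn", "rho"] == pytest.approx(-1.0)
        assert res.loc["up", "direction"] == "positive"
        assert res.loc["flat", "direction"] == "ns"
        assert "constant" in res.loc["flat", "note"]

    def test_matches_scipy_per_feature(self, rng):
        X = rng.gamma(1.0, 1.0, size=(15, 40))
        alt = rng.uniform(0, 1, 40)
        table = pd.DataFrame(X, index=[f"f{i}" for i in range(15)],
                             columns=[f"s{j}" for j in range(40)])
        res = spearman_screen(table, alt)
        for i in range(15):
            rho, p = stats.spearmanr(X[i], alt)
            assert res.iloc[i]["rho"] == pytest.approx(rho, abs=1e-12)
            assert res.iloc[i]["p_raw"] == pytest.approx(p, rel=1e-9)

    def test_invariant_to_monotone_transforms(self, rng):
        X = rng.gamma(1.0, 1.0, size=(5, 30)) + 0.1
        alt = rng.uniform(0, 1, 30)
        t1 = pd.DataFrame(X, columns=[f"s{j}" for j in range(30)])
        t2 = pd.DataFrame(np.exp(X), columns=t1.columns)
        r1 = spearman_screen(t1, np.log(alt + 1.0))
        r2 = spearman_screen(t2, alt)
        np.testing.assert_allclose(r1["rho"], r2["rho"], atol=1e-12)


class TestBH:
    def test_examples(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    def test_matches_statsmodels_and_is_monotone(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-6, 1, 300)
        adj = bh_adjust(p)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, expected, atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p).all()

    def test_discoveries_monotone_in_alpha(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        adj = bh_adjust(p)
        counts = [(adj < a).sum() for a in (0.01, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts)
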