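"""Gibbs samplers for the Gaussian models, contrasts and transforms."""

import numpy as np
import pandas as pd
import pytest

from neohybrid import (
    DataError,
    DomainError,
    LinearModelSpec,
    fit_gaussian_lm,
    fit_group_means,
    fit_varying_slopes,
    ols_t_intervals,
    slope_percent_change,
)

FAST = dict(draws=400, warmup=400, chains=2, seed=3)


def lm_data(n=200, beta=0.4, sigma=0.3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    y = 1.0 + beta * x + rng.normal(0, sigma, n)
    return pd.DataFrame({"y": y, "x": x})


class TestGaussianLm:
    def test_noiseless_linear_relation_recovered_sharply(self):
        x = np.linspace(1, 10, 40)
        df = pd.DataFrame({"y": 2.0 * x, "x": x})
        fit = fit_gaussian_lm(df, LinearModelSpec("y", ["x"]), **FAST)
        b = fit.summaries["b_x"]
        assert b.mean == pytest.approx(2.0, abs=0.01)
        assert b.sd < 0.01
        assert b.clarity

    def test_known_slope_inside_interval(self):
        fit = fit_gaussian_lm(lm_data(), LinearModelSpec("y", ["x"]), **FAST)
        lo, hi = fit.summaries["b_x"].ci95
        assert lo <= 0.4 <= hi

    def test_matches_analytic_posterior(self):
        df = lm_data(n=300, seed=2)
        spec = LinearModelSpec("y", ["x"])
        fit = fit_gaussian_lm(df, spec, draws=800, warmup=800, chains=2, seed=5)
        oracle = ols_t_intervals(df, spec)
        for name in ("alpha", "b_x"):
            assert fit.summaries[name].mean == pytest.approx(
                oracle[name]["estimate"], abs=0.01
            )
            lo, hi = fit.summaries[name].ci95
            olo, ohi = oracle[name]["ci"]
            assert lo == pytest.approx(olo, abs=0.02)
            assert hi == pytest.approx(ohi, abs=0.02)

    def test_constant_predictor_rejected(self):
        df = lm_data()
        df["x"] = 1.0
        with pytest.raises(DataError, match="constant"):
            fit_gaussian_lm(df, LinearModelSpec("y", ["x"]), **FAST)

    def test_zero_counts_dropped_under_log10(self):
        df = pd.DataFrame({"y": [1, 10, 100, 0, 5, 50], "x": [1, 10, 100, 5, 5, 50]})
        spec = LinearModelSpec("y", ["x"], transforms={"y": "log10", "x": "log10"})
        fit = fit_gaussian_lm(df, spec, **FAST)
        assert fit.report["n_dropped_zero"] == 1
        assert fit.report["n_rows_used"] == 5

    def test_negative_under_log10_is_a_data_error(self):
        df = pd.DataFrame({"y": [1.0, -2.0, 3.0, 4.0, 5.0], "x": [1, 2, 3, 4, 5]})
        spec = LinearModelSpec("y", ["x"], transforms={"y": "log10"})
        with pytest.raises(DataError, match="negative"):
            fit_gaussian_lm(df, spec, **FAST)

    def test_bit_stable_for_fixed_seed(self):
        df = lm_data(n=60)
        spec = LinearModelSpec("y", ["x"])
        f1 = fit_gaussian_lm(df, spec, **FAST)
        f2 = fit_gaussian_lm(df, spec, **FAST)
        np.testing.assert_array_equal(f1.summaries["b_x"].draws, f2.summaries["b_x"].draws)

    def test_interval_coverage_over_replicates(self):
        """95% interval covers a known slope in 90-99% of 100 replicates."""
        hits = 0
        for rep in range(100):
            df = lm_data(n=200, seed=1000 + rep)
            fit = fit_gaussian_lm(
                df, LinearModelSpec("y", ["x"]), draws=300, warmup=300, chains=2, seed=rep
            )
            lo, hi = fit.summaries["b_x"].ci95
            hits += lo <= 0.4 <= hi
        assert 90 <= hits <= 99


def rate_table(group_means=(0.05, 0.05, 0.15, 0.15), n_per=60, sigma=0.1, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in enumerate(group_means, start=1):
        log10_rate = np.log10(mu) + rng.normal(0, sigma, n_per)
        for v in log10_rate:
            rows.append(
                {
                    "genus": f"g{g}_{len(rows)}",
                    "group": g,
                    "log10_rate": v,
                    "monotypic": False,
                    "extreme": False,
                }
            )
    return pd.DataFrame(rows)


class TestGroupMeans:
    def test_planted_threefold_ratio_recovered(self):
        fit = fit_group_means(rate_table(), **FAST)
        c41 = next(c for c in fit.contrasts if set(c.pair) == {"both", "neither"})
        lo, hi = np.percentile(c41.ratio_draws, [2.5, 97.5])
        assert lo <= 3.0 <= hi

    def test_constant_difference_gives_exact_ratio(self):
        from neohybrid import Contrast

        c = Contrast(pair=("a", "b"), difference_draws=np.full(100, 0.30103))
        ratios = 10.0**c.difference_draws
        assert np.allclose(ratios, 2.0, atol=1e-4)

    def test_empty_group_is_an_error_naming_the_group(self):
        t = rate_table()
        t = t[t["group"] != 3]
        with pytest.raises(DataError, match="hybrids_only"):
            fit_group_means(t, **FAST)

    def test_monotypic_rows_excluded_by_default(self):
        t = rate_table(n_per=30)
        extra = t.iloc[:5].copy()
        extra["monotypic"] = True
        extra["log10_rate"] = np.nan
        fit = fit_group_means(pd.concat([t, extra], ignore_index=True), **FAST)
        assert fit.report["n_rows_used"] == len(t)

    def test_contrast_antisymmetry(self):
        fit = fit_group_means(rate_table(), **FAST)
        ab = fit.contrast("mu_both", "mu_neither")
        ba = fit.contrast("mu_neither", "mu_both")
        np.testing.assert_array_equal(ab.difference_draws, -ba.difference_draws)


def hfi_observations(
    offsets=(0.0, 2.0, 5.9), n_triplets=12, n_obs=25, sigma=3.0, seed=4
):
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_triplets):
        alpha = rng.normal(0, 1.5)
        for typ, off in zip(("native", "neophyte", "hybrid"), offsets):
            b = rng.normal(0, 0.8)
            for i, v in enumerate(22.6 + off + alpha + b + rng.normal(0, sigma, n_obs)):
                rows.append(
                    {
                        "triplet_id": f"T{t}",
                        "taxon_type": typ,
                        "hectad_code": f"{typ}{t}_{i}",
                        "hfi": v,
                    }
                )
    return pd.DataFrame(rows)


class TestVaryingSlopes:
    def test_planted_type_means_recovered(self):
        obs = hfi_observations()
        fit = fit_varying_slopes(obs, **FAST)
        for typ, off in zip(("native", "neophyte", "hybrid"), (0.0, 2.0, 5.9)):
            lo, hi = fit.summaries[f"mu_{typ}"].ci95
            assert lo <= 22.6 + off <= hi, typ

    def test_identical_hfi_gives_unclear_contrasts(self):
        obs = hfi_observations(offsets=(0, 0, 0), sigma=1e-6, n_triplets=4, n_obs=6, seed=9)
        rng = np.random.default_rng(0)
        obs["hfi"] = 20.0 + rng.normal(0, 1e-3, len(obs))  # no type signal
        fit = fit_varying_slopes(obs, **FAST)
        for c in fit.contrasts:
            lo, hi = np.percentile(c.difference_draws, [2.5, 97.5])
            assert lo <= 0 <= hi
            assert abs(np.mean(c.difference_draws)) < 0.01

    def test_contrasts_negate_consistently(self):
        fit = fit_varying_slopes(hfi_observations(), **FAST)
        hn = next(c for c in fit.contrasts if c.pair == ("hybrid", "native"))
        nh = fit.contrast("mu_native", "mu_hybrid")
        np.testing.assert_array_equal(hn.difference_draws, -nh.difference_draws)

    def test_single_triplet_rejected(self):
        obs = hfi_observations(n_triplets=1)
        with pytest.raises(DataError):
            fit_varying_slopes(obs, **FAST)


class TestSlopePercentChange:
    @pytest.mark.parametrize(
        "b,factor,expected",
        [(0.26, 1.2, 4.85), (0.64, 1.2, 12.38), (1.0, 1.2, 20.0), (0.0, 7.3, 0.0)],
    )
    def test_values(self, b, factor, expected):
        assert slope_percent_change(b, factor) == pytest.approx(expected, abs=0.01)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(DomainError):
            slope_percent_change(0.26, 0.0)
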