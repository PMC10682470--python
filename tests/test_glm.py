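import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from interactdeg.design import DesignError, DesignSpec
from interactdeg.glm import (
    GLMError,
    NBGLM,
    adjust_fdr,
    estimate_dispersion,
    estimate_size_factors,
    shrink_lfc,
    _normal_posterior_mode,
)
from interactdeg.simulate import NBScenario, simulate_counts


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 30, 7], "b": [10, 30, 7]})
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_library(self):
        """B = 2A: geometric mean is sqrt(2)*A, so factors are (1/sqrt2, sqrt2)."""
        counts = pd.DataFrame({"A": [10, 20, 50, 7], "B": [20, 40, 100, 14]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, [2**-0.5, 2**0.5])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, (50, 4)), columns=list("abcd"))
        sf = estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        sf2 = estimate_size_factors(scaled)
        # ratios between samples shift consistently: c's factor triples
        # relative to the others up to the common renormalisation
        assert np.allclose((sf2 / sf)["c"] / (sf2 / sf)["a"], 3.0)

    def test_all_genes_with_zeros_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(GLMError, match="filtering"):
            estimate_size_factors(counts)


class TestFit:
    def test_saturated_coefficients_are_log2_cell_mean_ratios(self, saturated_2x2):
        """Oracle: saturated fit reproduces observed cell means exactly."""
        counts, meta = saturated_2x2
        res = NBGLM(counts, meta, DesignSpec.with_interaction(), size_factors=1.0).fit()
        p = res.params.iloc[0]
        assert p["Intercept"] == pytest.approx(np.log2(100), abs=1e-6)
        assert p["diet[WD]"] == pytest.approx(1.0, abs=1e-6)
        assert p["weeks[6]"] == pytest.approx(0.0, abs=1e-6)
        assert p["diet[WD]:weeks[6]"] == pytest.approx(2.0, abs=1e-6)

    def test_constant_counts_give_zero_effects(self):
        counts = pd.DataFrame(
            [[50] * 8], index=["g"], columns=[f"s{i}" for i in range(8)]
        )
        meta = pd.DataFrame(
            {"diet": ["SD", "WD"] * 4, "weeks": [3, 3, 6, 6] * 2}, index=counts.columns
        )
        res = NBGLM(counts, meta, DesignSpec.with_interaction(), size_factors=1.0).fit()
        p = res.params.iloc[0]
        assert p["diet[WD]"] == pytest.approx(0.0, abs=1e-8)
        assert p["diet[WD]:weeks[6]"] == pytest.approx(0.0, abs=1e-8)

    def test_additive_design_forces_week_constant_diet_effect(self, small_nb_dataset):
        """Without the interaction term the fitted diet effect is the same at
        every week: the WD-SD difference of fitted log2 means is the single
        diet coefficient in each week."""
        counts, metadata, _ = small_nb_dataset
        res = NBGLM(counts, metadata, DesignSpec.additive()).fit()
        pred = res.predict_log2()  # samples x genes, q scale
        for week in (3, 6):
            sd = metadata.index[(metadata.weeks == week) & (metadata.diet == "SD")][0]
            wd = metadata.index[(metadata.weeks == week) & (metadata.diet == "WD")][0]
            diff = pred.loc[wd] - pred.loc[sd]
            assert np.allclose(diff, res.params["diet[WD]"], atol=1e-10)

    def test_sample_permutation_invariance(self, small_nb_dataset):
        counts, metadata, _ = small_nb_dataset
        res = NBGLM(counts, metadata, DesignSpec.with_interaction()).fit()
        perm = np.random.default_rng(1).permutation(counts.columns)
        res_p = NBGLM(counts[perm], metadata.loc[perm], DesignSpec.with_interaction()).fit()
        pd.testing.assert_frame_equal(res.params, res_p.params, atol=1e-9, rtol=0)
        pd.testing.assert_series_equal(res.dispersion, res_p.dispersion, atol=1e-9, rtol=0)

    def test_poisson_limit_matches_statsmodels_poisson(self, small_nb_dataset):
        """With tau fixed at the floor the fit coincides with a Poisson GLM."""
        import statsmodels.api as sm

        counts, metadata, _ = small_nb_dataset
        model = NBGLM(counts, metadata, DesignSpec.with_interaction())
        res = model.fit(dispersion=1e-8)
        X = model.exog.to_numpy()
        off = np.log(model.size_factors.to_numpy())
        for gene in counts.index[:5]:
            ref = sm.GLM(
                counts.loc[gene].to_numpy(), X, family=sm.families.Poisson(), offset=off
            ).fit()
            ours = res.params.loc[gene].to_numpy() * np.log(2)
            assert np.allclose(ours, ref.params, atol=1e-4)

    def test_fixed_dispersion_matches_statsmodels_nb(self, small_nb_dataset):
        """Independent oracle: statsmodels NB GLM at the same fixed tau."""
        import statsmodels.api as sm

        counts, metadata, _ = small_nb_dataset
        tau = 0.1
        model = NBGLM(counts, metadata, DesignSpec.with_interaction())
        res = model.fit(dispersion=tau)
        X = model.exog.to_numpy()
        off = np.log(model.size_factors.to_numpy())
        for gene in counts.index[5:10]:
            ref = sm.GLM(
                counts.loc[gene].to_numpy(),
                X,
                family=sm.families.NegativeBinomial(alpha=tau),
                offset=off,
            ).fit()
            assert np.allclose(res.params.loc[gene] * np.log(2), ref.params, atol=1e-4)
            assert np.allclose(res.bse.loc[gene] * np.log(2), ref.bse, rtol=1e-3)

    def test_degenerate_cell_flagged(self):
        counts = pd.DataFrame(
            [[0, 0, 40, 37, 52, 48, 61, 55], [20, 22, 40, 37, 52, 48, 61, 55]],
            index=["dead_cell", "fine"],
            columns=[f"s{i}" for i in range(8)],
        )
        meta = pd.DataFrame(
            {
                "diet": ["SD", "SD", "WD", "WD", "SD", "SD", "WD", "WD"],
                "weeks": [3, 3, 3, 3, 6, 6, 6, 6],
            },
            index=counts.columns,
        )
        res = NBGLM(counts, meta, DesignSpec.with_interaction(), size_factors=1.0).fit()
        assert "degenerate_cell" in res.flags["dead_cell"]
        assert res.flags["fine"] == ""
        tab = res.wald_test("diet[WD]:weeks[6]")
        assert np.isnan(tab.loc["dead_cell", "pvalue"])

    def test_empty_cell_raises_design_error(self):
        counts = pd.DataFrame(
            [[10, 12, 9, 11]], index=["g"], columns=["a", "b", "c", "d"]
        )
        meta = pd.DataFrame(
            {"diet": ["SD", "SD", "WD", "WD"], "weeks": [3, 6, 3, 3]},
            index=counts.columns,
        )
        with pytest.raises(DesignError, match="rank deficient"):
            NBGLM(counts, meta, DesignSpec.with_interaction())


class TestDispersion:
    def test_poisson_counts_hit_floor(self):
        sc = NBScenario.two_by_two(
            baseline_log2=np.full(30, np.log2(500.0)),
            dispersion=1e-10,
            n_per_cell=12,
            seed=21,
        )
        counts, meta = simulate_counts(sc)
        res = NBGLM(counts, meta, DesignSpec.with_interaction(), size_factors=1.0).fit()
        assert (res.dispersion < 5e-3).mean() > 0.8

    def test_recovery_within_50_percent(self):
        """tau = 0.2, 50 replicates, intercept-only: within 50% relative
        error for at least 90% of 200 independent genes (the Monte-Carlo
        calibration run)."""
        G, tau = 200, 0.2
        rng = np.random.default_rng(31)
        r = 1 / tau
        mu = 300.0
        K = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(G, 50)),
            index=[f"g{i}" for i in range(G)],
        )
        X = pd.DataFrame({"Intercept": np.ones(50)}, index=K.columns)
        tau_hat = estimate_dispersion(K, X, np.ones(50))
        rel_err = np.abs(tau_hat - tau) / tau
        assert (rel_err < 0.5).mean() >= 0.9


class TestWaldAndFDR:
    def test_zero_lfc_gives_p_one(self, saturated_2x2):
        counts, meta = saturated_2x2
        res = NBGLM(counts, meta, DesignSpec.with_interaction(), size_factors=1.0).fit()
        tab = res.wald_test("weeks[6]", shrink=False)  # true effect exactly 0
        assert tab["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_wald_quantile(self):
        # |z| = 1.959964 corresponds to two-sided p of 0.05
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_bh_worked_example(self):
        p = pd.Series([0.01, 0.02, 0.04])
        assert np.allclose(adjust_fdr(p), [0.03, 0.03, 0.04])

    def test_bh_single_and_degenerate(self):
        assert adjust_fdr(pd.Series([0.2])).iloc[0] == pytest.approx(0.2)
        assert (adjust_fdr(pd.Series([1.0, 1.0, 1.0])) == 1.0).all()

    def test_bh_nan_propagates(self):
        out = adjust_fdr(pd.Series([0.01, np.nan, 0.04]))
        assert np.isnan(out.iloc[1]) and out.notna().sum() == 2

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bh_bounds_property(self, pvals):
        p = pd.Series(pvals)
        out = adjust_fdr(p)
        assert ((out >= p - 1e-12) & (out <= 1 + 1e-12)).all()
        # monotone: sorting by p sorts the adjusted values
        order = np.argsort(p.to_numpy())
        assert (np.diff(out.to_numpy()[order]) >= -1e-12).all()


class TestShrinkage:
    def test_posterior_mode_closed_form(self):
        # ridge form raw * prior^2 / (prior^2 + se^2)
        assert _normal_posterior_mode(1.0, 1.0, 1.0) == pytest.approx(0.5)
        assert _normal_posterior_mode(0.0, 0.7, 1.3) == 0.0

    def test_precise_estimates_unaffected(self):
        lfc = pd.Series([2.0] + [0.0] * 20)
        se = pd.Series([1e-6] + [0.1] * 20)
        shrunk = shrink_lfc(lfc, se)
        assert shrunk.iloc[0] == pytest.approx(2.0, abs=1e-4)

    def test_degenerate_prior_falls_back_with_warning(self):
        lfc = pd.Series([0.01, -0.02, 0.015])
        se = pd.Series([1.0, 1.0, 1.0])  # spread far below noise
        with pytest.warns(RuntimeWarning, match="degenerate"):
            shrunk = shrink_lfc(lfc, se)
        pd.testing.assert_series_equal(shrunk, lfc)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=30),
        st.floats(0.01, 2.0),
    )
    def test_shrinkage_never_increases_magnitude(self, lfcs, se_scale):
        lfc = pd.Series(lfcs)
        se = pd.Series([se_scale] * len(lfcs))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shrunk = shrink_lfc(lfc, se)
        assert (shrunk.abs() <= lfc.abs() + 1e-12).all()
        assert (np.sign(shrunk) * np.sign(lfc) >= 0).all()


class TestParameterRecovery:
    def test_rmse_decreases_with_sample_size(self):
        rmses = []
        for n in (5, 20):
            sc = NBScenario.two_by_two(
                baseline_log2=np.full(300, np.log2(200.0)),
                diet_effect_wk6=1.0,
                dispersion=0.05,
                n_per_cell=n,
                seed=900 + n,
            )
            counts, meta = simulate_counts(sc)
            res = NBGLM(counts, meta, DesignSpec.with_interaction(), size_factors=1.0).fit()
            g = res.params["diet[WD]:weeks[6]"]
            rmses.append(float(np.sqrt(((g - 1.0) ** 2).mean())))
        assert rmses[1] < rmses[0]
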