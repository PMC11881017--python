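"""Bayesian persistence models: standardization, recovery, diagnostics.

Parameter-recovery tests simulate data from the model's own generative
process; landscape effects are rescaled to their exact target SD so that
recovery checks the sampler, not the luck of a particular random draw of
group effects.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evorescue.inference import (
    FixedPersistenceModel,
    HierarchicalPersistenceModel,
    InferenceError,
    InteractionPersistenceModel,
    Standardizer,
    slope_comparison,
    standardize,
)

FAST_FIT = dict(chains=3, warmup=800, draws=2400, thin=3)  # blocked hierarchical sampler
FAST_RW = dict(chains=3, warmup=800, draws=6000, thin=10)  # random-walk fixed-effects sampler


def exact_effects(rng, n, tau):
    """Zero-mean group effects with sample SD exactly tau."""
    u = rng.standard_normal(n)
    u -= u.mean()
    return u * (tau / u.std(ddof=1))


def simulate_hierarchical(rng, G=20, S=20, T=10, b0=-0.5, b1=1.0, tau0=0.5, tau1=0.3):
    u0 = exact_effects(rng, G, tau0) if tau0 > 0 else np.zeros(G)
    u1 = exact_effects(rng, G, tau1) if tau1 > 0 else np.zeros(G)
    land = np.repeat(np.arange(G), S)
    V = rng.normal(0, 1, G * S)
    z = (V - V.mean()) / V.std(ddof=1)
    eta = b0 + u0[land] + (b1 + u1[land]) * z
    k = rng.binomial(T, 1 / (1 + np.exp(-eta)))
    return pd.DataFrame(
        {"landscape_id": land, "scenario_id": np.arange(G * S), "V": V,
         "persisted": k, "trials": T}
    )


class TestStandardize:
    def test_sample_sd_convention(self):
        z, st = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert st.sd == 1.0

    def test_idempotence(self):
        z, _ = standardize([0.4, -1.1, 2.0, 0.1])
        z2, _ = standardize(z)
        np.testing.assert_allclose(z, z2, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])

    def test_roundtrip_and_slope_backmap(self):
        st = Standardizer.fit([3.0, 5.0, 9.0])
        v = np.array([4.2, 8.8])
        np.testing.assert_allclose(st.inverse(st.transform(v)), v)
        assert st.slope_to_natural(2.0) == pytest.approx(2.0 / st.sd)


class TestHierarchicalModel:
    def test_recovers_generating_values(self, rng):
        df = simulate_hierarchical(rng, G=25, S=25, T=15)
        res = HierarchicalPersistenceModel.from_frame(df, "V").fit(seed=1, **FAST_FIT)
        for name, truth in [("beta0", -0.5), ("beta1", 1.0), ("sd_intercept", 0.5), ("sd_slope", 0.3)]:
            lo, hi = res.posterior_interval(name)
            assert lo <= truth <= hi, f"{name}: [{lo:.3f}, {hi:.3f}] misses {truth}"

    def test_null_slope_interval_covers_zero(self, rng):
        df = simulate_hierarchical(rng, b1=0.0, G=15, S=15, T=10)
        res = HierarchicalPersistenceModel.from_frame(df, "V").fit(seed=2, **FAST_FIT)
        lo, hi = res.posterior_interval("beta1")
        assert lo <= 0.0 <= hi

    def test_degenerate_hierarchy_shrinks_sds(self, rng):
        # mixing at the tau -> 0 boundary is slower: run longer chains
        df = simulate_hierarchical(rng, tau0=0.0, tau1=0.0, G=25, S=30, T=20)
        res = HierarchicalPersistenceModel.from_frame(df, "V").fit(
            seed=3, chains=3, warmup=1200, draws=7200, thin=6
        )
        for name in ("sd_intercept", "sd_slope"):
            assert np.median(res._flat(name)) < 0.15

    def test_prior_predictive_matches_prior(self):
        """With no data the posterior over beta1 is its Normal(0, 5) prior."""
        model = HierarchicalPersistenceModel([], [], [], [])
        res = model.fit(seed=4, chains=2, warmup=1000, draws=4000, thin=2, check=False)
        draws = res._flat("beta1")
        ks = stats.kstest(draws, stats.norm(0, 5).cdf).statistic
        assert ks < 0.1

    def test_needs_three_landscapes(self):
        with pytest.raises(ValueError):
            HierarchicalPersistenceModel([1, 2], [5, 5], [0.1, 0.2], [0, 1])

    def test_diagnostics_failure_raises(self, rng):
        df = simulate_hierarchical(rng, G=10, S=10, T=5)
        model = HierarchicalPersistenceModel.from_frame(df, "V")
        with pytest.raises(InferenceError) as exc:
            model.fit(seed=5, chains=2, warmup=20, draws=60, thin=1)
        assert exc.value.diagnostics is not None

    def test_variational_cross_check(self, rng):
        """Independent oracle: statsmodels' variational Bayes mixed logit.

        Posterior means of the fixed effects from the MCMC fit should agree
        with the VB approximation on a well-identified dataset.
        """
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        df = simulate_hierarchical(rng, G=25, S=25, T=15)
        res = HierarchicalPersistenceModel.from_frame(df, "V").fit(seed=6, **FAST_FIT)
        z, _ = standardize(df["V"])
        long = pd.DataFrame(
            {
                "y": np.concatenate([np.ones(int(k)) for k in df["persisted"]] +
                                     [np.zeros(int(t - k)) for k, t in zip(df["persisted"], df["trials"])]),
                "V": np.concatenate([np.full(int(k), v) for k, v in zip(df["persisted"], z)] +
                                     [np.full(int(t - k), v) for k, t, v in zip(df["persisted"], df["trials"], z)]),
                "g": np.concatenate([np.full(int(k), g) for k, g in zip(df["persisted"], df["landscape_id"])] +
                                     [np.full(int(t - k), g) for k, t, g in zip(df["persisted"], df["trials"], df["landscape_id"])]),
            }
        )
        vb = BinomialBayesMixedGLM.from_formula(
            "y ~ V", {"a": "0 + C(g)", "b": "0 + C(g):V"}, long
        ).fit_vb()
        means = dict(zip(vb.model.exog_names, vb.fe_mean))
        assert res._flat("beta0").mean() == pytest.approx(means["Intercept"], abs=0.15)
        assert res._flat("beta1").mean() == pytest.approx(means["V"], abs=0.15)


class TestInteractionModel:
    def test_same_property_rejected(self):
        with pytest.raises(ValueError):
            InteractionPersistenceModel([1], [2], [0.1], [0.2], names=("x", "x"))

    def test_null_interaction_covers_zero(self, rng):
        n = 600
        v1, v2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        eta = 0.3 + 0.5 * v1 - 0.2 * v2
        k = rng.binomial(10, 1 / (1 + np.exp(-eta)))
        res = InteractionPersistenceModel(k, np.full(n, 10), v1, v2).fit(seed=7, **FAST_RW)
        lo, hi = res.posterior_interval("beta3")
        assert lo <= 0.0 <= hi

    def test_recovers_interaction(self, rng):
        n = 1200
        v1, v2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        z1 = (v1 - v1.mean()) / v1.std(ddof=1)
        z2 = (v2 - v2.mean()) / v2.std(ddof=1)
        eta = -0.2 + 0.4 * z1 + 0.1 * z2 + 0.8 * z1 * z2
        k = rng.binomial(20, 1 / (1 + np.exp(-eta)))
        res = InteractionPersistenceModel(k, np.full(n, 20), v1, v2).fit(seed=8, **FAST_RW)
        lo, hi = res.posterior_interval("beta3")
        assert lo <= 0.8 <= hi and lo > 0.0

    def test_standardization_backmap_matches_natural_fit(self, rng):
        """Slopes back-mapped from the z scale match an unstandardized fit."""
        n = 500
        v = 3.0 + 2.0 * rng.normal(0, 1, n)
        eta = 0.5 * (v - 3.0) / 2.0
        k = rng.binomial(20, 1 / (1 + np.exp(-eta)))
        res_z = FixedPersistenceModel(k, np.full(n, 20), v, name="V").fit(seed=9, **FAST_RW)
        st = res_z.standardizers["V"]
        natural = FixedPersistenceModel(
            k, np.full(n, 20), (v - v.mean()), name="V",
            standardizer=Standardizer(mean=0.0, sd=1.0),
        ).fit(seed=10, **FAST_FIT)
        mapped = st.slope_to_natural(res_z._flat("beta1").mean())
        assert mapped == pytest.approx(natural._flat("beta1").mean(), abs=0.03)


class TestSlopeComparison:
    def _fit(self, rng, slope, st=None):
        n = 300
        v = rng.normal(0, 1, n)
        k = rng.binomial(10, 1 / (1 + np.exp(-slope * v)))
        m = FixedPersistenceModel(k, np.full(n, 10), v, name="V",
                                  standardizer=st or Standardizer(0.0, 1.0))
        return m.fit(seed=11, chains=2, warmup=500, draws=1500, thin=3, check=False)

    def test_identical_fits_not_flagged(self, rng):
        fit = self._fit(rng, 0.5)
        table = slope_comparison({"control": fit, "p25": fit, "p75": fit})
        assert not table["non_overlapping_vs_control"].any()
        assert table["slope_mean"].nunique() == 1

    def test_constructed_interaction_orders_slopes(self, rng):
        st = Standardizer(0.0, 1.0)
        low = self._fit(rng, 0.1, st)
        high = self._fit(rng, 1.5, st)
        ctrl = self._fit(rng, 0.8, st)
        table = slope_comparison({"control": ctrl, "p25": low, "p75": high}).set_index("condition")
        assert table.loc["p25", "slope_mean"] < table.loc["p75", "slope_mean"]

    def test_missing_control_is_an_error(self, rng):
        with pytest.raises(ValueError):
            slope_comparison({"p25": self._fit(rng, 0.5)})

    def test_mismatched_standardization_rejected(self, rng):
        a = self._fit(rng, 0.5, Standardizer(0.0, 1.0))
        b = self._fit(rng, 0.5, Standardizer(2.0, 3.0))
        with pytest.raises(ValueError):
            slope_comparison({"control": a, "p25": b})

    def test_forest_plot_smoke(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        ax = self._fit(rng, 0.5).plot_forest()
        assert ax.get_xlabel() == "posterior (logit scale)"

    def test_draws_roundtrip_npz(self, rng, tmp_path):
        fit = self._fit(rng, 0.5)
        path = tmp_path / "draws.npz"
        fit.save_draws(path)
        loaded = np.load(path)
        np.testing.assert_array_equal(loaded["beta1"], fit.draws["beta1"])
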