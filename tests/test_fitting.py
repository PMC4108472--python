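"""Nonlinear fitting, nested model selection, and bootstrap uncertainty."""

import math

import numpy as np
import pytest

from bchekit import (
    KineticModelSelector,
    KineticParameters,
    MichaelisMentenRegressor,
    RateCurve,
    TwoSiteRegressor,
    bootstrap_uncertainty,
    fit_michaelis,
    fit_two_site,
    generate_rate_curve,
    select_model,
)
from tests.conftest import PROBAND, USUAL


def grid_search_rss(s, v, km_grid):
    """Exhaustive least-squares oracle over a Km lattice.

    For the Michaelian law at fixed Km the model is linear in Vmax, so the
    conditionally optimal Vmax = Σ(v·g)/Σ(g²) with g = S/(Km+S) is exact;
    the search is therefore exhaustive over the full (Vmax, Km) surface.
    """
    g = s[None, :] / (km_grid[:, None] + s[None, :])
    vmax_opt = (g @ v) / np.sum(g * g, axis=1)
    rss = np.sum((vmax_opt[:, None] * g - v[None, :]) ** 2, axis=1)
    i = int(np.argmin(rss))
    return float(rss[i]), float(vmax_opt[i]), float(km_grid[i])


class TestMichaelianFit:
    def test_noiseless_exact_recovery(self, noiseless_michaelian_curve):
        r = fit_michaelis(noiseless_michaelian_curve)
        assert r.converged
        assert r.params.vmax == pytest.approx(0.50, rel=1e-6)
        assert r.params.km_um == pytest.approx(265.0, rel=1e-6)
        assert r.rss < 1e-12

    def test_noisy_recovery_within_published_band(self):
        curve = generate_rate_curve(PROBAND, noise_cv=0.03, replicates=3, seed=7)
        r = fit_michaelis(curve)
        assert r.converged
        assert abs(r.params.km_um - 265.0) < 25.0
        assert r.std_errors["km"] is not None and r.std_errors["km"] > 0

    def test_grid_search_oracle_agreement(self):
        """The continuous optimum must sit within one lattice step of an
        exhaustive search on a small synthetic curve."""
        design = np.geomspace(10, 50_000, 8)
        curve = generate_rate_curve(
            PROBAND, design=design, noise_cv=0.03, replicates=1, seed=11
        )
        r = fit_michaelis(curve)
        km_grid = np.linspace(150.0, 400.0, 501)   # step 0.5
        rss_star, vmax_star, km_star = grid_search_rss(curve.s_um, curve.v, km_grid)
        assert abs(r.params.km_um - km_star) <= 0.5 + 1e-12
        assert r.params.vmax == pytest.approx(vmax_star, rel=1e-3)
        assert r.rss <= rss_star + 1e-12

    def test_too_few_concentrations_rejected(self):
        curve = RateCurve(s_um=[10, 100, 1000, 10_000], v=[0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="distinct"):
            fit_michaelis(curve)

    def test_order_invariance(self, noisy_usual_curve):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(noisy_usual_curve))
        shuffled = RateCurve(
            s_um=noisy_usual_curve.s_um[perm], v=noisy_usual_curve.v[perm]
        )
        a = fit_michaelis(noisy_usual_curve)
        b = fit_michaelis(shuffled)
        assert a.params.km_um == pytest.approx(b.params.km_um, rel=1e-6)

    def test_rate_rescaling_scales_vmax_only(self, noisy_usual_curve):
        scaled = RateCurve(s_um=noisy_usual_curve.s_um, v=noisy_usual_curve.v * 3.0)
        a = fit_two_site(noisy_usual_curve)
        b = fit_two_site(scaled)
        assert b.params.vmax == pytest.approx(3.0 * a.params.vmax, rel=1e-5)
        assert b.params.km_um == pytest.approx(a.params.km_um, rel=1e-5)
        assert b.params.kss_mm == pytest.approx(a.params.kss_mm, rel=1e-4)
        assert b.params.b == pytest.approx(a.params.b, rel=1e-5)


class TestTwoSiteFit:
    def test_noiseless_exact_recovery(self):
        truth = KineticParameters(vmax=7.51, km_um=21.0, kss_mm=0.49, b=2.4)
        curve = generate_rate_curve(truth, noise_cv=0.0, replicates=1, seed=0)
        r = fit_two_site(curve)
        assert r.converged
        assert r.params.vmax == pytest.approx(7.51, rel=1e-6)
        assert r.params.km_um == pytest.approx(21.0, rel=1e-6)
        assert r.params.kss_mm == pytest.approx(0.49, rel=1e-6)
        assert r.params.b == pytest.approx(2.4, rel=1e-6)

    def test_noisy_b_recovery_within_published_band(self):
        """The substrate-activation factor recovered from noisy usual-enzyme
        curves stays inside the published 3.2 ± 0.1 interval (median over a
        handful of seeded curves; single-curve estimates scatter wider)."""
        bs = []
        for seed in range(15):
            curve = generate_rate_curve(USUAL, noise_cv=0.03, replicates=3,
                                        seed=seed)
            r = fit_two_site(curve)
            assert r.converged
            bs.append(r.params.b)
        assert abs(float(np.median(bs)) - 3.2) < 0.1

    def test_nesting_rss_never_above_michaelian(self):
        for seed in range(5):
            curve = generate_rate_curve(USUAL, noise_cv=0.05, seed=seed)
            mm, ts = fit_michaelis(curve), fit_two_site(curve)
            assert ts.rss <= mm.rss + 1e-10

    def test_too_few_concentrations_rejected(self):
        design = np.geomspace(10, 50_000, 7)
        curve = generate_rate_curve(USUAL, design=design, noise_cv=0.0,
                                    replicates=1, seed=0)
        with pytest.raises(ValueError, match="distinct"):
            fit_two_site(curve)

    def test_low_substrate_only_design_flags_identifiability(self):
        design = np.geomspace(10, 900, 9)  # nothing above 1 mM
        curve = generate_rate_curve(USUAL, design=design, noise_cv=0.0,
                                    replicates=1, seed=0)
        est = TwoSiteRegressor().fit(curve.s_um, curve.v)
        assert est.identifiability_warning_

    def test_sklearn_protocol(self):
        curve = generate_rate_curve(USUAL, noise_cv=0.02, seed=1)
        est = TwoSiteRegressor()
        assert est.get_params()["weighting"] == "unweighted"
        est.set_params(weighting="proportional").fit(
            curve.s_um.reshape(-1, 1), curve.v
        )
        pred = est.predict(np.array([[100.0], [1000.0]]))
        assert pred.shape == (2,)
        assert np.all(pred > 0)


class TestModelSelection:
    def test_noiseless_michaelian_keeps_simple_model(
        self, noiseless_michaelian_curve
    ):
        r = select_model(noiseless_michaelian_curve)
        assert r.model == "michaelian"
        assert r.selection["chosen"] == "michaelian"

    def test_two_site_truth_selects_full_model(self):
        curve = generate_rate_curve(USUAL, noise_cv=0.03, seed=9)
        r = select_model(curve)
        assert r.model == "two_site"
        assert r.selection["p_value"] < 0.05

    def test_selector_estimator_interface(self):
        curve = generate_rate_curve(USUAL, noise_cv=0.03, seed=9)
        sel = KineticModelSelector(alpha=0.05).fit(curve.s_um, curve.v)
        assert sel.model_ == "two_site"
        assert sel.f_statistic_ > 0
        assert sel.predict(np.array([1000.0])).shape == (1,)

    def test_invalid_alpha_rejected(self):
        curve = generate_rate_curve(USUAL, noise_cv=0.03, seed=9)
        with pytest.raises(ValueError):
            KineticModelSelector(alpha=1.5).fit(curve.s_um, curve.v)


class TestBootstrap:
    def test_fixed_seed_reproduces_intervals(self):
        curve = generate_rate_curve(PROBAND, noise_cv=0.03, seed=4)
        fit = fit_michaelis(curve)
        a = bootstrap_uncertainty(curve, fit, B=60, seed=123)
        b = bootstrap_uncertainty(curve, fit, B=60, seed=123)
        assert a == b

    def test_interval_width_shrinks_with_noise(self):
        widths = []
        for cv in (0.06, 0.01):
            curve = generate_rate_curve(PROBAND, noise_cv=cv, seed=8)
            fit = fit_michaelis(curve)
            lo, hi = bootstrap_uncertainty(curve, fit, B=100, seed=1)["km"]
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_coverage_of_generative_km(self):
        """Nominal-68% percentile intervals cover the generative Km at a
        rate consistent with their level (between 55% and 80%)."""
        hits, n = 0, 100
        for i in range(n):
            curve = generate_rate_curve(PROBAND, noise_cv=0.03, seed=5000 + i)
            fit = fit_michaelis(curve)
            lo, hi = bootstrap_uncertainty(curve, fit, B=199, seed=i)["km"]
            hits += lo <= 265.0 <= hi
        assert 0.55 * n <= hits <= 0.80 * n

    def test_small_b_rejected(self):
        curve = generate_rate_curve(PROBAND, noise_cv=0.03, seed=4)
        fit = fit_michaelis(curve)
        with pytest.raises(ValueError):
            bootstrap_uncertainty(curve, fit, B=49, seed=0)

    def test_requires_converged_fit(self):
        curve = generate_rate_curve(PROBAND, noise_cv=0.03, seed=4)
        from bchekit.fitting import FitResult

        bad = FitResult(
            model="michaelian", params=None, std_errors={}, rss=math.inf,
            n_points=len(curve), converged=False,
        )
        with pytest.raises(ValueError):
            bootstrap_uncertainty(curve, bad, B=100, seed=0)
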