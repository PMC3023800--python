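"""Estimator round-trips, initial guesses, oracle equivalence and coverage."""

import numpy as np
import pytest

import stabfit as sf
from stabfit import fitting


class TestGuessEquilibriumInit:
    def test_midpoint_guess_near_truth(self, eq_truth, eq_curve):
        d, y = eq_curve
        g = sf.guess_equilibrium_init(d, y, eq_truth.temperature)
        assert g.cm == pytest.approx(eq_truth.cm, rel=0.10)

    def test_order_invariance(self, eq_truth, eq_curve):
        d, y = eq_curve
        g1 = sf.guess_equilibrium_init(d, y, eq_truth.temperature)
        g2 = sf.guess_equilibrium_init(d[::-1], y[::-1], eq_truth.temperature)
        assert g1 == g2

    def test_no_transition_in_linear_signal(self):
        d = np.linspace(0, 6, 15)
        with pytest.raises(fitting.NoTransitionError):
            sf.guess_equilibrium_init(d, 2.0 - 0.5 * d, 293.15)


class TestEquilibriumFit:
    def test_noiseless_round_trip(self, eq_truth, eq_curve):
        d, y = eq_curve
        res = sf.fit_equilibrium_curve(d, y, eq_truth.temperature)
        p = res.params
        for name in ("dg_h2o", "m_value", "bn0", "bu0", "an", "au"):
            assert getattr(p, name) == pytest.approx(getattr(eq_truth, name), rel=1e-6)
        assert res.residual_ss < 1e-12 * np.sum(y**2)
        assert res.converged
        assert set(res.stderr) >= {"dg_h2o", "m_value", "cm"}

    def test_too_few_points_rejected(self, eq_truth):
        d = np.linspace(0, 6, 5)
        with pytest.raises(ValueError):
            sf.fit_equilibrium_curve(d, sf.equilibrium_signal(eq_truth, d),
                                     eq_truth.temperature)

    def test_midpoint_outside_range_flagged(self, eq_truth):
        # only the native baseline is sampled: no transition to fit
        d = np.linspace(0, 1.2, 12)
        y = sf.equilibrium_signal(eq_truth, d)
        with pytest.raises(fitting.NoTransitionError):
            sf.fit_equilibrium_curve(d, y, eq_truth.temperature)

    def test_affine_invariance_of_thermodynamics(self, eq_truth, eq_curve):
        d, y = eq_curve
        base = sf.fit_equilibrium_curve(d, y, eq_truth.temperature)
        scaled = sf.fit_equilibrium_curve(d, 3.7 * y + 11.0, eq_truth.temperature)
        assert scaled.params.dg_h2o == pytest.approx(base.params.dg_h2o, rel=1e-8)
        assert scaled.params.m_value == pytest.approx(base.params.m_value, rel=1e-8)
        assert scaled.params.cm == pytest.approx(base.params.cm, rel=1e-8)

    def test_coverage_of_standard_errors(self, eq_truth, eq_curve):
        """3-sigma intervals cover the true dG(H2O) in >= 90% of replicates."""
        d, clean = eq_curve
        hits = 0
        n = 200
        for seed in range(n):
            rng = np.random.default_rng(seed)
            res = sf.fit_equilibrium_curve(d, clean + rng.normal(0, 0.1, d.size),
                                           eq_truth.temperature)
            if abs(res.params.dg_h2o - eq_truth.dg_h2o) <= 3 * res.stderr["dg_h2o"]:
                hits += 1
        assert hits / n >= 0.90


class TestStabilityCurveFit:
    def test_anchored_round_trip(self):
        truth = sf.StabilityCurveParams.anchored_at(dh_tm=827.0, dcp=11.0,
                                                    tm=87.3 + 273.15)
        t = np.array([283.15, 293.15, 303.15, 313.15, 323.15, 333.15])
        pts = list(zip(t, sf.stability_curve_dg(truth, t)))
        res = sf.fit_stability_curve(pts, anchor_tm=truth.t0)
        assert res.params.dh_t0 == pytest.approx(827.0, rel=1e-4)
        assert res.params.dcp == pytest.approx(11.0, rel=1e-4)
        assert res.params.anchored
        # constraint identity: the fitted curve crosses zero at the anchor
        assert abs(sf.stability_curve_dg(res.params, truth.t0)) < 1e-9

    def test_minimum_point_counts(self):
        pts = [(280.0, 50.0), (300.0, 60.0)]
        with pytest.raises(ValueError):
            sf.fit_stability_curve(pts, anchor_tm=380.0)
        with pytest.raises(ValueError):
            sf.fit_stability_curve(pts + [(310.0, 55.0), (320.0, 50.0)])

    def test_unanchored_fit_recovers_three_parameters(self, wt_stability):
        t = np.linspace(280.0, 340.0, 9)
        pts = list(zip(t, sf.stability_curve_dg(wt_stability, t)))
        res = sf.fit_stability_curve(pts, t0=wt_stability.t0)
        assert res.params.dh_t0 == pytest.approx(wt_stability.dh_t0, rel=1e-3)
        assert res.params.dcp == pytest.approx(wt_stability.dcp, rel=1e-3)


class TestKineticFit:
    def test_noiseless_round_trip(self, kinetic_truth):
        t = np.linspace(0.0, 600.0, 60)
        res = sf.fit_kinetic_trace(t, sf.kinetic_signal(kinetic_truth, t))
        assert res.params.k_app == pytest.approx(0.01, rel=1e-8)
        assert res.params.amplitude == pytest.approx(-5.0, rel=1e-8)
        assert res.params.a_inf == pytest.approx(-10.0, rel=1e-8)
        assert res.converged

    def test_monte_carlo_rate_accuracy(self, kinetic_truth):
        """Median relative error of k_app < 2% at 1%-of-amplitude noise."""
        t = np.linspace(0.0, 600.0, 60)
        clean = sf.kinetic_signal(kinetic_truth, t)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = sf.fit_kinetic_trace(t, clean + rng.normal(0, 0.05, t.size))
            errs.append(abs(res.params.k_app - 0.01) / 0.01)
        assert np.median(errs) < 0.02

    def test_constant_signal_rejected(self):
        t = np.linspace(0, 100, 20)
        with pytest.raises(fitting.FitError):
            sf.fit_kinetic_trace(t, np.full_like(t, -7.0))

    def test_short_span_flagged_nonconverged(self, kinetic_truth):
        t = np.linspace(0.0, 20.0, 30)  # span 20 s << 1/k = 100 s
        res = sf.fit_kinetic_trace(t, sf.kinetic_signal(kinetic_truth, t))
        assert not res.converged


class TestChevronFit:
    def test_exact_on_collinear_points(self):
        c = sf.ChevronParams(ln_ku_h2o=-23.587969848094, mu=2.5)
        d = np.array([4.0, 5.0, 6.0])
        res = sf.fit_chevron(d, np.exp(sf.chevron_ln_k(c, d)))
        assert res.params.ln_ku_h2o == pytest.approx(c.ln_ku_h2o, rel=1e-12)
        assert res.params.mu == pytest.approx(2.5, rel=1e-12)
        assert res.extra["ku_h2o"] == pytest.approx(np.exp(c.ln_ku_h2o), rel=1e-9)

    def test_matches_textbook_ols(self):
        rng = np.random.default_rng(7)
        d = np.array([3.0, 3.5, 4.0, 4.5, 5.0, 5.5])
        lnk = -20.0 + 2.2 * d + rng.normal(0, 0.05, d.size)
        res = sf.fit_chevron(d, np.exp(lnk))
        slope_ref, icpt_ref = np.polyfit(d, lnk, 1)
        assert res.params.mu == pytest.approx(slope_ref, rel=1e-12)
        assert res.params.ln_ku_h2o == pytest.approx(icpt_ref, rel=1e-12)

    def test_shift_equivariance(self):
        d = np.array([2.0, 3.0, 4.0, 5.0])
        lnk = np.array([-12.0, -10.1, -7.9, -6.2])
        base = sf.fit_chevron(d, np.exp(lnk))
        shifted = sf.fit_chevron(d, np.exp(lnk + 3.0))
        assert shifted.params.ln_ku_h2o - base.params.ln_ku_h2o == pytest.approx(3.0)
        assert shifted.params.mu == pytest.approx(base.params.mu)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sf.fit_chevron([4.0, 4.0, 5.0], [1e-5, 1.1e-5, 1e-4])
        with pytest.raises(ValueError):
            sf.fit_chevron([4.0, 5.0, 6.0], [1e-5, -1e-4, 1e-3])


class TestThermalMeltFit:
    def test_noiseless_round_trip_flat_baselines(self):
        truth = sf.ThermalMeltParams(tm=49.1 + 273.15, dhm=400.0,
                                     bn=0.0, bu=-10.0, an=0.0, au=0.0)
        t = np.arange(truth.tm - 25.0, truth.tm + 25.5, 1.0)
        res = sf.fit_thermal_melt(t, sf.thermal_signal(truth, t))
        assert abs(res.extra["tm_celsius"] - 49.1) < 0.01
        assert res.params.dhm == pytest.approx(400.0, rel=1e-4)

    def test_seeded_noise_keeps_tm_within_declared_error(self, melt_truth):
        """Tm scatter under 2%-of-amplitude noise stays below +-0.3 C."""
        t = np.arange(melt_truth.tm - 25.0, melt_truth.tm + 25.5, 1.0)
        clean = sf.thermal_signal(melt_truth, t)
        tms = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = sf.fit_thermal_melt(t, clean + rng.normal(0, 0.2, t.size))
            tms.append(res.extra["tm_celsius"])
        assert np.std(tms) < 0.3
        assert np.mean(tms) == pytest.approx(49.1, abs=0.3)

    def test_sign_flip_leaves_tm_unchanged(self, melt_truth):
        t = np.arange(melt_truth.tm - 25.0, melt_truth.tm + 25.5, 1.0)
        y = sf.thermal_signal(melt_truth, t)
        tm_up = sf.fit_thermal_melt(t, y).params.tm
        tm_dn = sf.fit_thermal_melt(t, -y).params.tm
        assert tm_up == pytest.approx(tm_dn, rel=1e-8)

    def test_no_transition_outside_scan(self, melt_truth):
        t = np.arange(melt_truth.tm + 25.0, melt_truth.tm + 45.0, 1.0)
        y = sf.thermal_signal(melt_truth, t)
        with pytest.raises((fitting.NoTransitionError, ValueError)):
            sf.fit_thermal_melt(t, y)


class TestGridSearchOracle:
    """The optimizer is at least as good as brute-force grid search on
    reduced two-parameter problems (baselines held at truth)."""

    def test_equilibrium(self, eq_truth, eq_curve):
        d, clean = eq_curve
        rng = np.random.default_rng(11)
        y = clean + rng.normal(0, 0.1, d.size)
        res = sf.fit_equilibrium_curve(d, y, eq_truth.temperature)
        best = np.inf
        for dg in np.linspace(20, 40, 200):
            for m in np.linspace(6, 14, 200):
                p = sf.TwoStateEqParams(dg, m, eq_truth.temperature,
                                        eq_truth.bn0, eq_truth.bu0,
                                        eq_truth.an, eq_truth.au)
                best = min(best, float(np.sum((sf.equilibrium_signal(p, d) - y) ** 2)))
        assert best >= res.residual_ss - 1e-6

    def test_stability_curve(self, wt_stability):
        t = np.linspace(283.15, 333.15, 6)
        rng = np.random.default_rng(12)
        dg = sf.stability_curve_dg(wt_stability, t) + rng.normal(0, 2.0, t.size)
        res = sf.fit_stability_curve(list(zip(t, dg)), anchor_tm=wt_stability.t0)
        best = np.inf
        for dh in np.linspace(700, 1100, 200):
            for dcp in np.linspace(5, 20, 200):
                c = sf.StabilityCurveParams.anchored_at(dh, dcp, wt_stability.t0)
                best = min(best, float(np.sum((sf.stability_curve_dg(c, t) - dg) ** 2)))
        assert best >= res.residual_ss - 1e-6

    def test_kinetic(self, kinetic_truth):
        t = np.linspace(0, 600, 60)
        rng = np.random.default_rng(13)
        y = sf.kinetic_signal(kinetic_truth, t) + rng.normal(0, 0.05, t.size)
        res = sf.fit_kinetic_trace(t, y)
        best = np.inf
        for k in np.linspace(0.005, 0.02, 200):
            for amp in np.linspace(-7, -3, 200):
                model = kinetic_truth.a_inf + amp * np.exp(-k * t)
                best = min(best, float(np.sum((model - y) ** 2)))
        assert best >= res.residual_ss - 1e-6

    def test_thermal_melt(self, melt_truth):
        t = np.arange(melt_truth.tm - 25.0, melt_truth.tm + 25.5, 1.0)
        rng = np.random.default_rng(14)
        y = sf.thermal_signal(melt_truth, t) + rng.normal(0, 0.2, t.size)
        res = sf.fit_thermal_melt(t, y)
        best = np.inf
        for tm in np.linspace(melt_truth.tm - 3, melt_truth.tm + 3, 200):
            for dhm in np.linspace(200, 700, 200):
                p = sf.ThermalMeltParams(tm, dhm, melt_truth.bn, melt_truth.bu,
                                         melt_truth.an, melt_truth.au)
                best = min(best, float(np.sum((sf.thermal_signal(p, t) - y) ** 2)))
        assert best >= res.residual_ss - 1e-6

    def test_chevron(self):
        d = np.array([3.0, 4.0, 5.0, 6.0])
        rng = np.random.default_rng(15)
        lnk = -15.0 + 2.0 * d + rng.normal(0, 0.1, d.size)
        res = sf.fit_chevron(d, np.exp(lnk))
        best = np.inf
        for icpt in np.linspace(-17, -13, 200):
            for mu in np.linspace(1.5, 2.5, 200):
                best = min(best, float(np.sum((icpt + mu * d - lnk) ** 2)))
        assert best >= res.residual_ss - 1e-6
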