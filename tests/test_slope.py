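"""Slope method: growth-phase detection, trimmed OLS, dose-response assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from exfrac.errors import InsufficientDataError
from exfrac.io import ConditionGroup
from exfrac.slope import (
    SlopeFractionRegressor,
    detect_growth_phase,
    fit_slope,
    slope_dose_response,
    slope_fit_group,
)

from conftest import make_well


def _group_from_od(od_traces, dt=0.25):
    wells = []
    for i, od in enumerate(od_traces):
        od = np.asarray(od, dtype=float)
        t = np.arange(od.size) * dt
        wells.append(make_well(t, od, np.zeros(od.size), well_id=f"W{i}"))
    return ConditionGroup("s", "IPTG", 1.0, wells)


def _od_for_mu(mu_per_rep, dt=0.25, od0=0.1):
    """OD traces whose forward-difference growth rates equal the given values."""
    traces = []
    for mus in mu_per_rep:
        od = [od0]
        for m in mus:
            od.append(od[-1] * (1.0 + m * dt))
        traces.append(od)
    return traces


class TestDetectGrowthPhase:
    def test_identical_zero_rates_are_excluded_with_p_one(self):
        g = _group_from_od(_od_for_mu([[0.0, 0.0]] * 3))
        mask = detect_growth_phase(g)
        assert not mask.included.any()
        assert np.allclose(mask.p_values, 1.0)

    def test_tight_positive_rates_are_included(self):
        # replicate mu {0.50, 0.52, 0.48, 0.50}: t = 0.5/ (0.01633/2) ~ 61.2
        g = _group_from_od(_od_for_mu([[0.50], [0.52], [0.48], [0.50]]))
        mask = detect_growth_phase(g, alpha=0.05)
        assert mask.included[0]
        assert mask.p_values[0] < 1e-4

    def test_rates_straddling_zero_are_excluded(self):
        g = _group_from_od(_od_for_mu([[0.01], [-0.02], [0.02], [-0.01]]))
        mask = detect_growth_phase(g, alpha=0.05)
        assert not mask.included[0]
        assert mask.p_values[0] > 0.05

    def test_significantly_negative_rates_are_excluded(self):
        g = _group_from_od(_od_for_mu([[-0.50], [-0.52], [-0.48], [-0.50]]))
        assert not detect_growth_phase(g).included[0]

    def test_single_replicate_falls_back_to_threshold_with_warning(self):
        g = _group_from_od(_od_for_mu([[0.5, 0.01]]))
        with pytest.warns(UserWarning, match="threshold"):
            mask = detect_growth_phase(g, mu_min=0.05)
        assert mask.included.tolist() == [True, False]


class TestFitSlope:
    def test_exact_line_through_origin(self):
        mu = np.linspace(0.1, 1.0, 10)
        fit = fit_slope(mu, 0.3 * mu)
        assert fit.slope == pytest.approx(0.3, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_trimmed == 0
        assert fit.b == pytest.approx(0.0, abs=1e-9)

    def test_exact_affine_data_recovers_slope_and_b(self):
        mu = np.linspace(0.2, 1.0, 12)
        fit = fit_slope(mu, 0.3 * (mu - 0.1))
        assert fit.slope == pytest.approx(0.3, abs=1e-12)
        assert fit.b == pytest.approx(0.1, abs=1e-10)

    @pytest.mark.parametrize("trim_rule", ["first_local_max", "global_max"])
    def test_hook_points_are_trimmed_and_slope_recovered(self, trim_rule):
        # 6 early points on a curve (inducer equilibration), then a clean line
        rng = np.random.default_rng(42)
        t = np.arange(26) * 0.25
        mu = np.linspace(0.9, 0.2, 26)
        rho = 0.25 * mu + rng.normal(0, 0.002, 26)
        rho[:6] = 0.25 * mu[:6] * np.linspace(0.05, 0.6, 6)  # the hook
        fit = fit_slope(mu, rho, times=t, trim_rule=trim_rule)
        assert fit.n_trimmed == 6
        assert abs(fit.slope - 0.25) < 3 * fit.slope_se

    def test_no_trim_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0.05, 1.0, 12)
            y = 0.2 * x + rng.normal(0, 0.01, 12)
            fit = fit_slope(x, y, trim=False)
            slope_ref, intercept_ref = np.polyfit(x, y, 1)
            assert fit.slope == pytest.approx(slope_ref, rel=1e-10)
            assert fit.intercept == pytest.approx(intercept_ref, rel=1e-10)

    def test_accepted_trims_strictly_increase_r_squared(self):
        rng = np.random.default_rng(3)
        mu = np.linspace(1.0, 0.1, 30)
        rho = 0.3 * mu + rng.normal(0, 0.01, 30)
        rho[:5] *= np.linspace(0.2, 0.8, 5)
        fit = fit_slope(mu, rho)
        r2_at = lambda d: fit_slope(mu[d:], rho[d:], trim=False).r_squared
        r2s = [r2_at(d) for d in range(fit.n_trimmed + 1)]
        assert all(b > a for a, b in zip(r2s, r2s[1:]))

    def test_through_origin_agrees_with_free_intercept_on_b0_data(self):
        rng = np.random.default_rng(7)
        mu = np.linspace(0.1, 1.0, 40)
        rho = 0.4 * mu + rng.normal(0, 0.005, 40)
        free = fit_slope(mu, rho, model="free_intercept", trim=False)
        origin = fit_slope(mu, rho, model="through_origin", trim=False)
        assert origin.intercept == 0.0 and origin.b == 0.0
        assert abs(origin.slope - free.slope) < free.slope_se

    def test_negative_slope_reports_b_zero_with_warning(self):
        mu = np.linspace(0.1, 1.0, 8)
        with pytest.warns(UserWarning, match="slope"):
            fit = fit_slope(mu, -0.2 * mu + 0.5, trim=False)
        assert fit.b == 0.0 and "non_positive_slope" in fit.flags

    def test_too_few_points_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_slope([0.1, 0.2, 0.3], [0.01, 0.02, 0.03])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_ols_matches_textbook_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1, 1, 15)
        y = rng.normal(0, 1, 15)
        fit = fit_slope(x, y, trim=False)
        dx = x - x.mean()
        slope = float(dx @ (y - y.mean())) / float(dx @ dx)
        assert fit.slope == pytest.approx(slope, rel=1e-10, abs=1e-12)

    def test_sklearn_estimator_protocol(self):
        est = SlopeFractionRegressor(model="through_origin", min_points=5)
        assert clone(est).get_params()["min_points"] == 5
        x = np.linspace(0.1, 1, 10)
        est.fit(x, 0.3 * x)
        assert np.allclose(est.predict([[0.5]]), 0.15)


def test_noiseless_simulated_culture_recovers_f_h_within_5_percent(noiseless_culture):
    cfg, group, _ = noiseless_culture
    fit = slope_fit_group(group, "gfp")
    f_h = cfg.f_h_truth(group.concentration)
    assert fit.slope / cfg.kappa == pytest.approx(f_h, rel=0.05)
    assert fit.r_squared > 0.99


def test_slope_dose_response_flags_low_r_squared(default_titration):
    cfg, titration = default_titration
    fits = [slope_fit_group(g, "gfp") for g in titration.groups]
    dr = slope_dose_response(fits, r2_floor=0.9)
    assert len(dr.table) == 6
    flagged = dr.table.loc[dr.table["f_h"] > 0, "flags"].str.contains("low_r_squared")
    # at default noise the pooled-rate R^2 sits below 0.9 for induced wells
    low = [f.r_squared for f in fits if f.concentration > 0 and f.r_squared < 0.9]
    assert flagged.sum() == len(low)
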