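"""Hill dose-response: evaluation identities, bounded weighted fitting, comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from exfrac.errors import InsufficientDataError
from exfrac.hill import (
    DoseResponse,
    HillParams,
    HillRegressor,
    compare_methods,
    fit_hill,
    hill_eval,
)


def _dr(conc, f_h, var=None, n=4, method="maximum"):
    conc = np.asarray(conc, dtype=float)
    var = np.ones_like(conc) if var is None else np.asarray(var, dtype=float)
    return DoseResponse(
        strain="BL21",
        inducer="IPTG",
        method=method,
        table=pd.DataFrame({"concentration": conc, "f_h": f_h, "variance": var, "n": n}),
    )


class TestHillEval:
    def test_zero_concentration_gives_zero_for_both_forms(self):
        for form in ("full", "reduced"):
            assert hill_eval(0.0, H=5.0, k_I=2.0, n=2.0, form=form) == 0.0

    def test_saturation_limits(self):
        big = 1e12
        assert hill_eval(big, H=5.0, k_I=2.0, n=2.0, form="full") == pytest.approx(5.0 / 6.0)
        assert hill_eval(big, H=5.0, k_I=2.0, n=2.0, form="reduced") == pytest.approx(5.0)

    @pytest.mark.parametrize("n", [1.0, 2.0, 5.5])
    def test_half_saturation_identity_for_reduced_form(self, n):
        assert hill_eval(3.0, H=8.0, k_I=3.0, n=n, form="reduced") == pytest.approx(4.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_eval(-1.0, H=1.0, k_I=1.0, n=1.0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        H=st.floats(0.01, 1e4), k=st.floats(1e-3, 1e3), n=st.floats(1.0, 8.0),
        form=st.sampled_from(["full", "reduced"]),
    )
    def test_monotonically_non_decreasing_in_concentration(self, H, k, n, form):
        I = np.logspace(-3, 4, 60)
        y = hill_eval(I, H=H, k_I=k, n=n, form=form)
        assert np.all(np.diff(y) >= -1e-12 * np.maximum(y[1:], 1e-300))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(H=st.floats(0.01, 50.0), k=st.floats(0.01, 100.0), n=st.floats(1.0, 6.0))
    def test_full_form_equals_rescaled_reduced_form(self, H, k, n):
        I = np.logspace(-2, 3, 30)
        full = hill_eval(I, H=H, k_I=k, n=n, form="full")
        reduced = hill_eval(
            I, H=H / (H + 1.0), k_I=k * (H + 1.0) ** (-1.0 / n), n=n, form="reduced"
        )
        assert np.allclose(full, reduced, rtol=1e-10)


class TestFitHill:
    def test_noiseless_recovery_to_four_significant_figures(self):
        H, k, n = 9784.0, 31.0, 2.5
        conc = np.array([0.0, 5.0, 10.0, 20.0, 31.0, 60.0, 120.0, 500.0])
        y = hill_eval(conc, H=H, k_I=k, n=n, form="reduced")
        p = fit_hill(_dr(conc, y))
        assert p.H == pytest.approx(H, rel=5e-4)
        assert p.k_I == pytest.approx(k, rel=5e-4)
        assert p.n == pytest.approx(n, rel=5e-4)
        assert p.converged

    def test_sub_cooperative_data_hits_the_n_bound_and_matches_profile_oracle(self):
        conc = np.array([0.0, 2.0, 5.0, 10.0, 25.0, 60.0, 150.0, 400.0])
        y = hill_eval(conc, H=100.0, k_I=20.0, n=0.8, form="reduced")
        p = fit_hill(_dr(conc, y))
        assert p.n == pytest.approx(1.0, abs=1e-6)  # active bound

        # independent oracle: profile the weighted RSS over an (n, k) grid with
        # H solved in closed form (the model is linear in H)
        def rss(nn, kk):
            g = hill_eval(conc, H=1.0, k_I=kk, n=nn, form="reduced")
            H_hat = float(g @ y) / float(g @ g)
            return float(np.sum((y - H_hat * g) ** 2))

        grid = [(nn, kk) for nn in np.linspace(1.0, 3.0, 41) for kk in np.linspace(5, 60, 111)]
        best = min(grid, key=lambda t: rss(*t))
        assert best[0] == 1.0  # oracle also pins n at the bound
        assert p.rss <= rss(*best) + 1e-9

    def test_flat_response_is_flagged_non_identifiable(self):
        conc = np.array([0.0, 1.0, 10.0, 100.0, 1000.0])
        y = np.array([0.0, 50.0, 50.0, 50.0, 50.0])
        with pytest.warns(UserWarning, match="identifiable"):
            p = fit_hill(_dr(conc, y))
        assert "non_identifiable_k_I" in p.flags
        assert p.H == pytest.approx(50.0, rel=1e-3)

    def test_equal_weights_match_unweighted_fit(self):
        rng = np.random.default_rng(1)
        conc = np.array([0.0, 5.0, 15.0, 30.0, 60.0, 120.0])
        y = hill_eval(conc, H=50.0, k_I=30.0, n=2.0, form="reduced") * rng.lognormal(0, 0.05, 6)
        w = fit_hill(_dr(conc, y, var=np.full(6, 3.7)))
        est = HillRegressor().fit(conc, y)
        assert w.H == pytest.approx(est.H_, rel=1e-8)
        assert w.k_I == pytest.approx(est.k_I_, rel=1e-8)
        assert w.n == pytest.approx(est.n_, rel=1e-8)

    def test_zero_variance_points_get_median_variance_with_warning(self):
        conc = np.array([0.0, 5.0, 15.0, 30.0, 60.0, 120.0])
        y = hill_eval(conc, H=50.0, k_I=30.0, n=2.0, form="reduced")
        with pytest.warns(UserWarning, match="median"):
            p = fit_hill(_dr(conc, y, var=[0.0, 1.0, 1.0, 1.0, 1.0, 1.0]))
        assert p.converged

    def test_too_few_distinct_concentrations_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_hill(_dr([0.0, 1.0, 2.0], [0, 1, 2]))

    def test_parameter_recovery_under_5_percent_noise(self):
        # 100 titrations of 6 concentrations straddling k_I, N = 4 replicates
        H, k, n = 1.0, 30.0, 2.5
        conc = np.array([0.0, 10.0, 20.0, 40.0, 80.0, 160.0])
        truth = hill_eval(conc, H=H, k_I=k, n=n, form="reduced")
        k_err, n_err = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            reps = truth[None, :] * rng.lognormal(0.0, 0.05, (4, conc.size))
            y = reps.mean(axis=0)
            var = reps.var(axis=0, ddof=1)
            p = fit_hill(_dr(conc, y, var=var))
            k_err.append(abs(p.k_I - k) / k)
            n_err.append(abs(p.n - n))
        assert np.median(k_err) < 0.10
        assert np.median(n_err) < 0.5

    def test_sklearn_estimator_protocol(self):
        est = HillRegressor(form="full")
        assert clone(est).get_params()["form"] == "full"
        conc = np.array([0.0, 1.0, 3.0, 10.0, 30.0])
        y = hill_eval(conc, H=4.0, k_I=3.0, n=2.0, form="full")
        est.fit(conc.reshape(-1, 1), y)
        assert np.allclose(est.predict(conc.reshape(-1, 1)), y, atol=1e-6)


class TestCompareMethods:
    def test_identical_parameters_give_zero_differences(self):
        p = HillParams(H=10.0, k_I=2.0, n=1.5, se_H=1.0, se_kI=0.1, se_n=0.1)
        cmp_rec = compare_methods(p, p)
        assert np.allclose(cmp_rec.table["abs_diff"], 0.0)
        assert np.allclose(cmp_rec.table["z"], 0.0)

    def test_published_scale_arithmetic(self):
        a = HillParams(H=9784.0, k_I=31.0, n=2.5, se_H=191.0, se_kI=3.7, se_n=0.3)
        b = HillParams(H=8457.0, k_I=35.6, n=2.5, se_H=225.0, se_kI=5.5, se_n=0.5)
        row = compare_methods(a, b).table.set_index("parameter").loc["H"]
        assert row["rel_diff"] == pytest.approx(0.1356, abs=0.001)
        assert row["z"] == pytest.approx(4.5, abs=0.05)
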