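"""Self-validation experiments: the package analysing its own simulator.

Each function sets up a ground-truthed synthetic scenario, runs the ordinary
analysis path on it, and reports the discrepancy between what the analysis
recovered and what the generator put in. They are used by the test suite and
by ``scripts/acceptance.py``; every random draw descends from the ``seed``
argument.
"""

from __future__ import annotations

import warnings

import numpy as np

from .hill import fit_hill, hill_eval
from .io import ConditionGroup
from .kinetics import specific_growth_rate, specific_production_rate
from .maxima import find_phi_max, max_dose_response
from .simulate import SimConfig, simulate_titration, simulate_trajectory
from .slope import fit_slope, slope_dose_response, slope_fit_group

#: Titration design used throughout: six concentrations straddling the
#: generator's apparent affinity (k_I = 30), zero point included.
TITRATION_CONCS = (0.0, 10.0, 20.0, 40.0, 80.0, 160.0)


def theorem_fixed_point(seed: int = 0) -> dict[str, float]:
    """Interior-maximum check: at the peak of phi_H, phi_H equals f_H.

    Simulates noiseless cultures in which reporter production shuts down
    while growth continues (so phi_H has a genuine interior maximum), locates
    the maximum on the integration grid, and reports the worst relative
    mismatch between phi_H and the instantaneous expression fraction there.
    """
    worst = 0.0
    for I in (40.0, 160.0):
        cfg = SimConfig(noise_od=0.0, noise_flu=0.0, arrest_S=4.0, arrest_rate=0.5, seed=seed)
        traj = simulate_trajectory(cfg, I, return_fine=True)
        phi, f_h = traj["fine_phi_H"], traj["fine_f_H"]
        i = int(np.argmax(phi))
        if not 0 < i < phi.size - 1:
            raise RuntimeError("scenario failed to produce an interior maximum")
        worst = max(worst, abs(phi[i] - f_h[i]) / f_h[i])
    return {"rel_err_pct": 100.0 * worst, "n": phi.size}


def slope_method_recovery(n_titrations: int = 100, seed: int = 0) -> dict[str, float]:
    """Parameter recovery through the full slope-method pipeline.

    For each titration: simulate (4 replicates, 5% fluorescence noise, OD at
    the instrument default), run growth-phase detection + trimmed slope fits,
    assemble the dose-response, fit the reduced Hill law, and compare the
    recovered (k_I, n) with the generating values.
    """
    k_errs, n_errs = [], []
    base = int(seed) % 2**20
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_titrations):
            cfg = SimConfig(noise_flu=0.05, seed=base + i)
            titration = simulate_titration(cfg, TITRATION_CONCS)
            fits = [slope_fit_group(g, "gfp") for g in titration.groups]
            params = fit_hill(slope_dose_response(fits))
            k_errs.append(abs(params.k_I - cfg.hill_kI) / cfg.hill_kI)
            n_errs.append(abs(params.n - cfg.hill_n))
    return {
        "median_k_I_rel_err_pct": 100.0 * float(np.median(k_errs)),
        "median_n_abs_err": float(np.median(n_errs)),
        "n": n_titrations,
    }


def method_concordance(seed: int = 0) -> dict[str, float]:
    """Maximum vs slope method on one default titration (b = 0, no inducer lag).

    Returns the per-parameter z-scores between the two Hill fits and the
    relative differences of the estimates.
    """
    from .hill import compare_methods

    cfg = SimConfig(seed=int(seed) % 2**20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        titration = simulate_titration(cfg, TITRATION_CONCS)
        slope_fits = [slope_fit_group(g, "gfp") for g in titration.groups]
        max_results = [find_phi_max(g, "gfp") for g in titration.groups]
        p_slope = fit_hill(slope_dose_response(slope_fits))
        p_max = fit_hill(max_dose_response(max_results))
    table = compare_methods(p_max, p_slope).table.set_index("parameter")
    return {
        "z_H": float(table.loc["H", "z"]),
        "z_k_I": float(table.loc["k_I", "z"]),
        "z_n": float(table.loc["n", "z"]),
        "max_abs_z": float(table["z"].abs().max()),
        "rel_diff_H_pct": 100.0 * float(table.loc["H", "rel_diff"]),
        "rel_diff_k_I_pct": 100.0 * float(table.loc["k_I", "rel_diff"]),
        "n": int(len(TITRATION_CONCS)),
    }


def estimator_oracles(seed: int = 0) -> dict[str, float]:
    """Exactness checks of the low-level estimators against independent oracles."""
    from .io import WellTimeSeries

    # forward-difference growth rate on a printed toy input: 0.1 -> 0.11 in 0.25 h
    w = WellTimeSeries("A1", np.array([0.0, 0.25]), np.array([0.1, 0.11]), {"gfp": np.array([0.0, 0.0])})
    _, mu = specific_growth_rate(w)
    mu_err = abs(mu[0] - 0.4)

    # production rate: flu 100 -> 180 over 0.25 h at OD 0.2 gives 1600
    w2 = WellTimeSeries("A1", np.array([0.0, 0.25]), np.array([0.2, 0.2]), {"gfp": np.array([100.0, 180.0])})
    _, rho = specific_production_rate(w2, "gfp")
    rho_err = abs(rho[0] - 1600.0)

    # untrimmed OLS vs the textbook closed form on random instances
    rng = np.random.default_rng(int(seed) % 2**31)
    ols_err = 0.0
    for _ in range(50):
        x = rng.uniform(0.05, 1.0, 12)
        y = 0.3 * x + rng.normal(0.0, 0.02, 12)
        fit = fit_slope(x, y, trim=False)
        dx = x - x.mean()
        slope_ref = float(dx @ (y - y.mean())) / float(dx @ dx)
        ols_err = max(ols_err, abs(fit.slope - slope_ref) / abs(slope_ref))

    # bounded Hill fit vs a profile-scan oracle on sub-cooperative data (n bound active)
    conc = np.array([0.0, 2.0, 5.0, 10.0, 25.0, 60.0, 150.0, 400.0])
    y = hill_eval(conc, H=100.0, k_I=20.0, n=0.8, form="reduced")
    from .hill import HillRegressor

    est = HillRegressor().fit(conc, y)

    def profile_rss(nn, kk):
        g = hill_eval(conc, H=1.0, k_I=kk, n=nn, form="reduced")
        return float(np.sum((y - (g @ y) / (g @ g) * g) ** 2))

    grid_best = min(
        (profile_rss(nn, kk) for nn in np.linspace(1.0, 3.0, 41) for kk in np.linspace(5.0, 60.0, 111))
    )
    return {
        "growth_rate_abs_err": float(mu_err),
        "production_rate_abs_err": float(rho_err),
        "ols_max_rel_err": float(ols_err),
        "hill_n_bound_gap": float(abs(est.n_ - 1.0)),
        "hill_rss_vs_profile_oracle": float(est.rss_ - grid_best),
        "n": 50,
    }


def conservation_checks(seed: int = 0) -> dict[str, float]:
    """Simplex conservation and the frozen-coefficient closed form."""
    from scipy.integrate import cumulative_simpson

    simplex_dev = 0.0
    closed_dev = 0.0
    for I in (0.0, 30.0, 160.0):
        cfg = SimConfig(noise_od=0.0, noise_flu=0.0, seed=seed)
        traj = simulate_trajectory(cfg, I, return_fine=True)
        total = traj["phi_R"] + traj["phi_C"] + traj["phi_Q"] + traj["phi_H"]
        simplex_dev = max(simplex_dev, float(np.max(np.abs(total - 1.0))))
        # constant f_H makes phi_H(t) = F (1 - exp(-int rho)) exact
        F = float(cfg.f_h_truth(I))
        integral = cumulative_simpson(traj["fine_rho"], x=traj["fine_t"], initial=0.0)
        closed = F * (1.0 - np.exp(-integral))
        closed_dev = max(closed_dev, float(np.max(np.abs(traj["fine_phi_H"] - closed))))
    return {
        "simplex_max_abs_dev": simplex_dev,
        "closed_form_max_abs_dev": closed_dev,
        "n": int(traj["fine_t"].size),
    }
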