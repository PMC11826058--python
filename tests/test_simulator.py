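"""Allocation-model simulator: conservation laws, closed forms, determinism."""

import numpy as np
import pytest
from scipy.integrate import cumulative_simpson, solve_ivp

from exfrac.simulate import (
    SimConfig,
    initial_state,
    simulate_culture,
    simulate_titration,
    simulate_trajectory,
    step_model,
    _derivs,
)


def _simplex_dev(traj):
    total = traj["phi_R"] + traj["phi_C"] + traj["phi_Q"] + traj["phi_H"]
    return float(np.max(np.abs(total - 1.0)))


class TestDynamics:
    def test_uninduced_reporter_fraction_stays_zero(self):
        traj = simulate_trajectory(SimConfig(noise_od=0, noise_flu=0), 0.0)
        assert np.all(traj["phi_H"] == 0.0)
        assert np.all(traj["f_H"] == 0.0)

    @pytest.mark.parametrize("I", [0.0, 20.0, 160.0])
    def test_proteome_simplex_is_conserved(self, I):
        traj = simulate_trajectory(SimConfig(equilibration_tau=0.5), I)
        assert _simplex_dev(traj) < 1e-6

    def test_phi_h_matches_frozen_coefficient_closed_form(self):
        # with constant f_H = F and phi_H(0) = 0, Eq.-of-motion integrates to
        # phi_H(t) = F * (1 - exp(-int_0^t rho)) for any rho(t)
        cfg = SimConfig(noise_od=0, noise_flu=0)
        traj = simulate_trajectory(cfg, 160.0, return_fine=True)
        F = float(cfg.f_h_truth(160.0))
        integral = cumulative_simpson(traj["fine_rho"], x=traj["fine_t"], initial=0.0)
        closed = F * (1.0 - np.exp(-integral))
        assert np.max(np.abs(traj["fine_phi_H"] - closed)) < 1e-6

    def test_rk4_matches_adaptive_reference_integrator(self):
        cfg = SimConfig(noise_od=0, noise_flu=0)
        I = np.asarray([80.0])
        y0 = initial_state(cfg).vector()
        ref = solve_ivp(
            lambda t, y: _derivs(y[:, None], cfg, I)[:, 0],
            (0.0, cfg.t_end), y0, rtol=1e-10, atol=1e-12, dense_output=True,
        )
        traj = simulate_trajectory(cfg, 80.0)
        y_ref = ref.sol(traj["t"])
        assert np.max(np.abs(traj["M"] - y_ref[0])) < 1e-5 * np.max(y_ref[0])
        assert np.max(np.abs(traj["phi_H"] - y_ref[6])) < 1e-6

    def test_halving_the_substep_barely_changes_sampled_outputs(self):
        cfg = SimConfig(noise_od=0, noise_flu=0)
        a = simulate_trajectory(cfg, 80.0, n_substeps=cfg.n_substeps)
        b = simulate_trajectory(cfg, 80.0, n_substeps=2 * cfg.n_substeps)
        od_a, od_b = cfg.c_od * a["M"], cfg.c_od * b["M"]
        flu_a, flu_b = cfg.kappa_flu * a["phi_H"] * a["M"], cfg.kappa_flu * b["phi_H"] * b["M"]
        assert np.max(np.abs(od_a - od_b) / od_b) < 1e-5
        scale = np.maximum(flu_b, np.max(flu_b) * 1e-6)
        assert np.max(np.abs(flu_a - flu_b) / scale) < 1e-5

    def test_step_model_is_consistent_with_trajectory(self):
        cfg = SimConfig(noise_od=0, noise_flu=0)
        state = initial_state(cfg)
        dt = cfg.dt_sample / cfg.n_substeps
        for _ in range(cfg.n_substeps):
            state = step_model(state, cfg, 40.0, dt)
        traj = simulate_trajectory(cfg, 40.0)
        assert state.M == pytest.approx(traj["M"][1], rel=1e-12)
        assert state.phi_R + state.phi_C + state.phi_Q + state.phi_H == pytest.approx(1.0, abs=1e-9)

    def test_theorem_interior_maximum_equals_expression_fraction(self):
        # production arrest creates an interior phi_H maximum; there phi_H = f_H
        cfg = SimConfig(noise_od=0, noise_flu=0, arrest_S=4.0, arrest_rate=0.5)
        traj = simulate_trajectory(cfg, 160.0, return_fine=True)
        phi, f_h = traj["fine_phi_H"], traj["fine_f_H"]
        i = int(np.argmax(phi))
        assert 0 < i < phi.size - 1  # interior
        assert abs(phi[i] - f_h[i]) / f_h[i] < 0.01

    def test_equilibration_lag_produces_the_early_hook(self):
        from exfrac.kinetics import rate_series
        from exfrac.io import ConditionGroup

        def early_ratio_deficit(tau, I=30.0):
            # near k_I the internal-inducer lag depresses early production;
            # far above k_I the lag is invisible (saturation), as observed
            cfg = SimConfig(noise_od=0, noise_flu=0, equilibration_tau=tau, n_replicates=1)
            (well,) = simulate_culture(cfg, I)
            rs = rate_series(well, "gfp")
            grow = rs.mu > 0.05
            ratio = rs.rho_h[grow] / rs.mu[grow]
            return float(np.min(ratio[:3]) / np.median(ratio))

        assert early_ratio_deficit(0.0) == pytest.approx(1.0, abs=0.05)
        assert early_ratio_deficit(0.7) < 0.5  # early points fall below the line
        # the lag shortens with concentration: deficit is milder at saturation
        assert early_ratio_deficit(0.7, I=160.0) > early_ratio_deficit(0.7, I=30.0)


class TestObservationModel:
    def test_noiseless_uninduced_culture(self):
        cfg = SimConfig(noise_od=0.0, noise_flu=0.0)
        wells = simulate_culture(cfg, 0.0)
        for w in wells:
            assert np.all(w.fluorescence["gfp"] == 0.0)
            d = np.diff(w.od600)
            assert np.all(d > -1e-12)  # strictly increasing until exhaustion, then flat

    def test_same_seed_is_bit_identical(self):
        cfg = SimConfig(seed=123)
        a = simulate_culture(cfg, 40.0)
        b = simulate_culture(cfg, 40.0)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.od600, wb.od600)
            assert np.array_equal(wa.fluorescence["gfp"], wb.fluorescence["gfp"])

    def test_different_replicates_differ_only_by_noise(self):
        cfg = SimConfig(seed=123)
        a, b = simulate_culture(cfg, 40.0)[:2]
        assert not np.array_equal(a.od600, b.od600)
        assert np.allclose(a.od600, b.od600, rtol=0.2)

    def test_maturation_delay_shifts_fluorescence_later(self):
        slow = SimConfig(noise_od=0, noise_flu=0, maturation_time=1.0)
        fast = SimConfig(noise_od=0, noise_flu=0)
        (ws,) = simulate_culture(slow, 160.0)[:1]
        (wf,) = simulate_culture(fast, 160.0)[:1]
        assert np.all(ws.fluorescence["gfp"] <= wf.fluorescence["gfp"] + 1e-9)
        # the delayed trace catches up to within ~exp(-dt/tau) after growth stops
        assert ws.fluorescence["gfp"][-1] > 0.8 * wf.fluorescence["gfp"][-1]


class TestTitration:
    def test_default_design_counts(self, default_titration):
        _, tit = default_titration
        wells = [s for g in tit.groups for s in g.series]
        assert len(wells) == 24  # 6 concentrations x 4 replicates
        assert all(w.n_samples == 65 for w in wells)  # 16 h at 15-min sampling

    def test_ground_truth_half_saturation_identity(self):
        cfg = SimConfig()
        tit = simulate_titration(cfg, [0.0, cfg.hill_kI, 4 * cfg.hill_kI])
        row = tit.truth.loc[tit.truth.concentration == cfg.hill_kI].iloc[0]
        assert row["f_h"] == pytest.approx(cfg.hill_H / 2.0)

    def test_config_validation_rejects_overfull_proteome(self):
        with pytest.raises(ValueError):
            SimConfig(f_Q=0.5, hill_H=0.6)
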