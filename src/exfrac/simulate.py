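"""Batch-culture simulator for synthetic biosensor plate-reader data.

The cell is modelled as four proteome fractions — ribosomal/biosynthetic
``phi_R``, nutrient-fixing ``phi_C``, structural ``phi_Q`` (constant share)
and heterologous ``phi_H`` — whose shares evolve with the biosynthesis rate
``rho`` as

    d(phi_i)/dt = rho * (f_i - phi_i),

where ``f_i`` is the expression fraction: the share of the current
biosynthesis flux allocated to group i. The concrete batch-culture closure
used here (one consistent instantiation of that framework, with Monod-type
kinetics throughout):

    rho    = k_rho * phi_R * x / (K_x + x)          biosynthesis
    uptake = Y * phi_C * S / (K_S + S)              nutrient fixation (per biomass)
    f_H    = hill(I * I_int) * g                    inducer-controlled allocation
    rest   = 1 - f_Q - f_H;  a = x / (alloc_Kx + x)
    f_R    = rest * a;  f_C = rest * (1 - a)        precursor level x stimulates
                                                    f_R and represses f_C
    dx/dt  = uptake - rho - mu * x                  precursor balance (per biomass)
    dM/dt  = mu * M;  dS/dt = -uptake * M;  mu = rho

``mu = rho`` encodes protein mass proportional to biomass. ``I_int`` is the
internal inducer fraction, approaching 1 with first-order time constant
``equilibration_tau`` (0 disables the lag; a positive lag produces the early
"hook" in rho_H-vs-mu plots). ``g`` is an optional production-arrest factor
that decays once nutrients fall below ``arrest_S`` while growth continues
(emulating reporters whose synthesis stops before growth does, the source of
a positive x-axis intercept b).

Observations: OD600 = c_od * M and fluorescence = kappa_flu * phi_H * M,
sampled every ``dt_sample`` (default every 15 min for 16 h, as in microtiter
experiments), each multiplied by lognormal noise. Integration is fixed-step
RK4 on ``n_substeps`` substeps per sampling interval — deterministic and
accurate for these smooth batch dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataQualityError
from .hill import hill_eval
from .io import ConditionGroup, WellAnnotation, WellTimeSeries, write_layout_csv, write_tidy_csv, series_to_frame

__all__ = [
    "SimConfig",
    "SimState",
    "step_model",
    "simulate_trajectory",
    "simulate_culture",
    "simulate_titration",
    "TitrationResult",
]

# state vector layout
_M, _S, _X, _PR, _PC, _PQ, _PH, _IINT, _G = range(9)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the allocation model and of the synthetic plate reader.

    Ground-truth dose-response: ``f_H(I) = hill_H * I^n / (I^n + hill_kI^n)``
    on the fraction scale, so ``hill_H`` must leave room next to the constant
    structural share (``hill_H + f_Q <= 1``).
    """

    # allocation / regulation
    f_Q: float = 0.45            # constant structural expression fraction
    hill_H: float = 0.12         # max heterologous expression fraction
    hill_kI: float = 30.0        # apparent affinity, concentration units
    hill_n: float = 2.5          # Hill coefficient
    alloc_Kx: float = 0.5        # precursor level at which f_R/f_C split equally
    # metabolism
    Y: float = 9.0               # nutrient fixation rate (precursor/h per unit phi_C)
    K_S: float = 0.25            # nutrient half-saturation
    k_rho: float = 3.0           # max biosynthesis rate (1/h per unit phi_R)
    K_x: float = 0.5             # precursor half-saturation
    # initial conditions
    S0: float = 8.0              # initial nutrient; exhaustion within ~8-12 h
    M0: float = 0.1              # initial biomass (OD-proportional units)
    x0: float = 0.3              # initial precursor per biomass
    # inducer transport / production arrest
    equilibration_tau: float = 0.0   # h; 0 = instantaneous inducer import
    arrest_S: float = 0.0            # nutrient level triggering production arrest (0 = off)
    arrest_rate: float = 0.0         # 1/h first-order decay of f_H once triggered
    # observation model
    c_od: float = 1.0            # OD600 per biomass unit
    kappa_flu: float = 8.0e4     # fluorescence per (phi_H * biomass)
    maturation_time: float = 0.0  # h; first-order fluorophore maturation
    noise_od: float = 0.01       # lognormal sigma, OD channel
    noise_flu: float = 0.02      # lognormal sigma, fluorescence channel
    # sampling
    dt_sample: float = 0.25      # h between plate-reader readings
    t_end: float = 16.0          # h of culture
    n_replicates: int = 4
    seed: int = 0
    n_substeps: int = 25         # RK4 substeps per sampling interval
    strain: str = "sim"
    inducer: str = "IPTG"
    conc_unit: str = "uM"
    channel: str = "gfp"

    def __post_init__(self) -> None:
        if not 0 < self.f_Q < 1:
            raise ValueError("f_Q must be in (0, 1)")
        if not 0 <= self.hill_H <= 1 - self.f_Q:
            raise ValueError("hill_H must satisfy 0 <= hill_H <= 1 - f_Q")
        for name in ("Y", "K_S", "k_rho", "K_x", "alloc_Kx", "S0", "M0", "dt_sample", "kappa_flu", "c_od"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dt_sample > self.t_end:
            raise ValueError("dt_sample must not exceed t_end")

    def f_h_truth(self, I) -> float | np.ndarray:
        """Ground-truth equilibrated expression fraction at concentration(s) I."""
        return hill_eval(I, H=self.hill_H, k_I=self.hill_kI, n=self.hill_n, form="reduced")

    @property
    def kappa(self) -> float:
        """Fluorescence-per-phi_H scale in flu/OD units (kappa_flu / c_od)."""
        return self.kappa_flu / self.c_od


@dataclass
class SimState:
    """Instantaneous model state."""

    t: float
    M: float
    S: float
    x: float
    phi_R: float
    phi_C: float
    phi_Q: float
    phi_H: float
    I_int: float = 1.0
    g: float = 1.0

    def vector(self) -> np.ndarray:
        return np.array(
            [self.M, self.S, self.x, self.phi_R, self.phi_C, self.phi_Q, self.phi_H, self.I_int, self.g]
        )


def initial_state(config: SimConfig) -> SimState:
    """Freshly induced culture: no reporter yet, native fractions split by x0."""
    a = config.x0 / (config.alloc_Kx + config.x0)
    rest = 1.0 - config.f_Q
    return SimState(
        t=0.0,
        M=config.M0,
        S=config.S0,
        x=config.x0,
        phi_R=rest * a,
        phi_C=rest * (1.0 - a),
        phi_Q=config.f_Q,
        phi_H=0.0,
        I_int=1.0 if config.equilibration_tau == 0 else 0.0,
        g=1.0,
    )


def _derivs(y: np.ndarray, config: SimConfig, I: np.ndarray) -> np.ndarray:
    """Right-hand side; ``y`` has shape (9, k) for k parallel conditions."""
    M, S, x = y[_M], np.maximum(y[_S], 0.0), np.maximum(y[_X], 0.0)
    phi_R, phi_C, phi_Q, phi_H = y[_PR], y[_PC], y[_PQ], y[_PH]
    I_int, g = y[_IINT], y[_G]

    rho = config.k_rho * phi_R * x / (config.K_x + x)
    uptake = config.Y * phi_C * S / (config.K_S + S)
    f_H = hill_eval(
        np.maximum(I * I_int, 0.0), H=config.hill_H, k_I=config.hill_kI,
        n=config.hill_n, form="reduced",
    ) * g
    rest = 1.0 - config.f_Q - f_H
    a = x / (config.alloc_Kx + x)
    f_R = rest * a
    f_C = rest * (1.0 - a)

    dy = np.empty_like(y)
    dy[_M] = rho * M
    dy[_S] = -uptake * M
    dy[_X] = uptake - rho - rho * x
    dy[_PR] = rho * (f_R - phi_R)
    dy[_PC] = rho * (f_C - phi_C)
    dy[_PQ] = rho * (config.f_Q - phi_Q)
    dy[_PH] = rho * (f_H - phi_H)
    if config.equilibration_tau > 0:
        dy[_IINT] = (1.0 - I_int) / config.equilibration_tau
    else:
        dy[_IINT] = 0.0
    if config.arrest_rate > 0 and config.arrest_S > 0:
        dy[_G] = np.where(S < config.arrest_S, -config.arrest_rate * g, 0.0)
    else:
        dy[_G] = 0.0
    return dy


def _rk4(y: np.ndarray, config: SimConfig, I: np.ndarray, dt: float) -> np.ndarray:
    k1 = _derivs(y, config, I)
    k2 = _derivs(y + 0.5 * dt * k1, config, I)
    k3 = _derivs(y + 0.5 * dt * k2, config, I)
    k4 = _derivs(y + dt * k3, config, I)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


_NEG_TOL = -1e-9


def _step_checked(y: np.ndarray, config: SimConfig, I: np.ndarray, dt: float) -> np.ndarray:
    """One RK4 step; on a negative state, retry once at dt/10 substeps."""
    y1 = _rk4(y, config, I, dt)
    if np.min(y1) < _NEG_TOL:
        y1 = y.copy()
        for _ in range(10):
            y1 = _rk4(y1, config, I, dt / 10.0)
        if np.min(y1) < _NEG_TOL:
            raise DataQualityError(
                f"integration step dt={dt} produced a negative state even after refinement; "
                "reduce the step size"
            )
    return np.maximum(y1, 0.0)


def step_model(state: SimState, config: SimConfig, I: float, dt: float) -> SimState:
    """Advance the model by one step of length ``dt`` (single RK4 substep)."""
    if dt > config.dt_sample:
        raise ValueError("dt must not exceed dt_sample")
    y = _step_checked(state.vector()[:, None], config, np.asarray([float(I)]), dt)[:, 0]
    return SimState(state.t + dt, *map(float, y))


def simulate_trajectory(
    config: SimConfig,
    I,
    n_substeps: int | None = None,
    return_fine: bool = False,
) -> dict[str, np.ndarray]:
    """Integrate the deterministic model for one or more inducer concentrations.

    Returns a dict of arrays on the sampling grid: ``t`` (n_t,), and
    ``M, S, x, phi_R, phi_C, phi_Q, phi_H, f_H, rho, mu`` each of shape
    (n_t, k) for k concentrations (squeezed to (n_t,) for a scalar ``I``).
    ``f_H`` is the instantaneous expression fraction, recorded so that
    analysis results can be checked against the generating truth. With
    ``return_fine`` the same arrays on the integration grid are attached
    under ``fine_*`` keys.
    """
    scalar = np.isscalar(I)
    I_arr = np.atleast_1d(np.asarray(I, dtype=float))
    nsub = config.n_substeps if n_substeps is None else n_substeps
    dt = config.dt_sample / nsub
    n_t = int(round(config.t_end / config.dt_sample)) + 1

    y = np.tile(initial_state(config).vector()[:, None], (1, I_arr.size))
    fine_t, fine_y = [0.0], [y.copy()]
    for _ in range((n_t - 1) * nsub):
        y = _step_checked(y, config, I_arr, dt)
        fine_t.append(fine_t[-1] + dt)
        fine_y.append(y.copy())
    fine_t_arr = np.asarray(fine_t)
    fine_Y = np.stack(fine_y)  # (n_fine, 9, k)

    def extract(Yt: np.ndarray, t: np.ndarray) -> dict[str, np.ndarray]:
        out = {
            "t": t,
            "M": Yt[:, _M],
            "S": Yt[:, _S],
            "x": Yt[:, _X],
            "phi_R": Yt[:, _PR],
            "phi_C": Yt[:, _PC],
            "phi_Q": Yt[:, _PQ],
            "phi_H": Yt[:, _PH],
            "I_int": Yt[:, _IINT],
            "g": Yt[:, _G],
        }
        out["f_H"] = (
            hill_eval(
                np.maximum(I_arr[None, :] * out["I_int"], 0.0),
                H=config.hill_H, k_I=config.hill_kI, n=config.hill_n, form="reduced",
            )
            * out["g"]
        )
        xx = out["x"]
        out["rho"] = config.k_rho * out["phi_R"] * xx / (config.K_x + xx)
        out["mu"] = out["rho"]
        return out

    sample_idx = np.arange(0, (n_t - 1) * nsub + 1, nsub)
    result = extract(fine_Y[sample_idx], fine_t_arr[sample_idx])
    if return_fine:
        fine = extract(fine_Y, fine_t_arr)
        result.update({f"fine_{k}": v for k, v in fine.items()})
    if scalar:
        result = {k: (v[..., 0] if v.ndim > 1 else v) for k, v in result.items()}
    return result


def _mature(signal: np.ndarray, t: np.ndarray, tau: float) -> np.ndarray:
    """First-order maturation filter (exact update for piecewise-constant input)."""
    if tau <= 0:
        return signal
    out = np.empty_like(signal)
    out[0] = 0.0
    decay = np.exp(-np.diff(t) / tau)
    for i in range(1, signal.size):
        out[i] = signal[i] + (out[i - 1] - signal[i]) * decay[i - 1]
    return out


def simulate_culture(
    config: SimConfig,
    I: float,
    return_truth: bool = False,
    _noise_key: tuple[int, ...] = (0,),
):
    """Simulate replicate wells at one inducer concentration.

    Returns ``n_replicates`` :class:`~exfrac.io.WellTimeSeries` (and, with
    ``return_truth``, the noiseless trajectory dict from
    :func:`simulate_trajectory`). The deterministic trajectory is shared by
    the replicates; only the multiplicative lognormal observation noise
    differs, drawn from per-replicate substreams of ``config.seed``.
    """
    nsub = config.n_substeps
    traj = simulate_trajectory(config, float(I), return_fine=config.maturation_time > 0)
    t = traj["t"]
    od_clean = config.c_od * traj["M"]
    if config.maturation_time > 0:
        fine_flu = config.kappa_flu * traj["fine_phi_H"] * traj["fine_M"]
        matured = _mature(fine_flu, traj["fine_t"], config.maturation_time)
        flu_clean = matured[::nsub]
    else:
        flu_clean = config.kappa_flu * traj["phi_H"] * traj["M"]

    wells = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, *(_noise_key), rep])
        od = od_clean * np.exp(config.noise_od * rng.standard_normal(t.size)) if config.noise_od > 0 else od_clean.copy()
        flu = flu_clean * np.exp(config.noise_flu * rng.standard_normal(t.size)) if config.noise_flu > 0 else flu_clean.copy()
        wells.append(
            WellTimeSeries(
                well_id=f"R{rep + 1}",
                times=t.copy(),
                od600=od,
                fluorescence={config.channel: flu},
            )
        )
    if return_truth:
        return wells, traj
    return wells


def _well_ids(n: int):
    """A1..H12, then P2-A1.. for overflow beyond one 96-well plate."""
    ids = []
    plate = 1
    while len(ids) < n:
        for r in range(8):
            for c in range(12):
                coord = f"{chr(65 + r)}{c + 1}"
                ids.append(coord if plate == 1 else f"P{plate}-{coord}")
                if len(ids) == n:
                    return ids
        plate += 1
    return ids


@dataclass
class TitrationResult:
    """In-memory synthetic titration: groups, tidy frames and ground truth."""

    groups: list[ConditionGroup]
    annotations: list[WellAnnotation]
    truth: pd.DataFrame
    config: SimConfig
    strain_configs: dict[str, SimConfig] = field(default_factory=dict)

    def data_frame(self) -> pd.DataFrame:
        return series_to_frame([s for g in self.groups for s in g.series])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write data/layout/ground-truth CSVs; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "data": outdir / "data.csv",
            "layout": outdir / "layout.csv",
            "truth": outdir / "ground_truth.csv",
        }
        write_tidy_csv(self.groups, paths["data"])
        write_layout_csv(self.annotations, paths["layout"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def simulate_titration(
    config: SimConfig,
    concentrations: Sequence[float],
    strains: Sequence[tuple[str, dict]] | None = None,
    outdir: str | Path | None = None,
    allow_degenerate: bool = False,
) -> TitrationResult:
    """Simulate a full titration design (optionally across several strains).

    ``strains`` is a list of (name, config-override dict) pairs; omitted, the
    single ``config.strain`` is used. Each (strain, concentration) condition
    gets ``n_replicates`` wells on a shared plate layout. The ground-truth
    table records the generating Hill parameters and the equilibrated
    ``f_H(I)`` per condition, both on the fraction scale and on the flu/OD
    scale (``kappa * f_H``).
    """
    concentrations = [float(c) for c in concentrations]
    if len(concentrations) < 3 and not allow_degenerate:
        raise ValueError("a titration needs at least 3 concentrations")
    if strains is None:
        strain_cfgs = {config.strain: config}
    else:
        strain_cfgs = {name: replace(config, strain=name, **over) for name, over in strains}

    n_wells = len(strain_cfgs) * len(concentrations) * config.n_replicates
    ids = iter(_well_ids(n_wells))
    groups, annotations, truth_rows = [], [], []
    for s_idx, (strain, cfg) in enumerate(strain_cfgs.items()):
        for c_idx, conc in enumerate(sorted(concentrations)):
            wells = simulate_culture(cfg, conc, _noise_key=(s_idx, c_idx))
            named = []
            for rep, w in enumerate(wells):
                wid = next(ids)
                named.append(WellTimeSeries(wid, w.times, w.od600, w.fluorescence))
                annotations.append(
                    WellAnnotation(
                        well_id=wid, strain=strain, inducer=cfg.inducer,
                        concentration=conc, conc_unit=cfg.conc_unit,
                        replicate=rep + 1, is_blank=False,
                    )
                )
            groups.append(
                ConditionGroup(strain=strain, inducer=cfg.inducer, concentration=conc,
                               series=named, conc_unit=cfg.conc_unit)
            )
            f_h = float(cfg.f_h_truth(conc))
            truth_rows.append(
                {
                    "strain": strain,
                    "inducer": cfg.inducer,
                    "concentration": conc,
                    "conc_unit": cfg.conc_unit,
                    "f_h": f_h,
                    "f_h_flu_od": cfg.kappa * f_h,
                    "hill_H": cfg.hill_H,
                    "hill_H_flu_od": cfg.kappa * cfg.hill_H,
                    "hill_kI": cfg.hill_kI,
                    "hill_n": cfg.hill_n,
                    "kappa": cfg.kappa,
                }
            )
    result = TitrationResult(
        groups=groups,
        annotations=annotations,
        truth=pd.DataFrame(truth_rows),
        config=config,
        strain_configs=strain_cfgs,
    )
    if outdir is not None:
        result.write(outdir)
    return result
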