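"""End-to-end orchestration: data (real or simulated) -> rates -> both methods -> Hill fits.

A single :class:`RunConfig` — normally loaded from YAML — drives the whole
analysis and writes a reproducible output directory:

* ``rates.csv`` — per-well mu, rho_H, phi_H
* ``max_method.csv`` / ``slope_method.csv`` — per-condition estimates
* ``hill_maximum.json`` / ``hill_slope.json`` — per-(strain, inducer) Hill fits
* ``comparison.csv`` — per-parameter method agreement (z-scores)
* ``plots/`` — phi_H(t) traces with marked maxima; rho_H-vs-mu scatters with
  trimmed points greyed and the fitted line (diagnostics only)
* ``manifest.json`` — config hash, seed, package/library versions, file list

Given the same config and seed, all CSV/JSON outputs are byte-identical
across runs; every random draw descends from the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ExfracError, InsufficientDataError
from .hill import DoseResponse, HillParams, compare_methods, fit_hill
from .io import blank_correct, read_tidy_csv
from .kinetics import rates_table
from .maxima import find_phi_max, max_dose_response, max_method_table
from .simulate import SimConfig, simulate_titration
from .slope import slope_dose_response, slope_fit_group, slope_method_table


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one input source.

    Either ``data_csv``/``layout_csv`` point at real measurements, or
    ``simulation`` holds SimConfig field overrides plus ``concentrations``.
    """

    # input: real data ...
    data_csv: str | None = None
    layout_csv: str | None = None
    # ... or simulation
    simulation: dict[str, Any] | None = None
    concentrations: list[float] = field(default_factory=list)

    channel: str = "gfp"
    maturation_time: dict[str, float] | float = 0.0
    blank_mode: str = "none"
    alpha: float = 0.05
    window_h: float = 10.0
    min_points: int = 4
    slope_model: str = "free_intercept"
    trim_rule: str = "first_local_max"
    hill_form: str = "reduced"
    outdir: str = "exfrac_run"
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        has_files = self.data_csv is not None or self.layout_csv is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError("exactly one of {data_csv+layout_csv, simulation} must be given")
        if has_files and (self.data_csv is None or self.layout_csv is None):
            raise ValueError("real-data runs need both data_csv and layout_csv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def maturation_for(self, channel: str) -> float:
        if isinstance(self.maturation_time, dict):
            return float(self.maturation_time.get(channel, 0.0))
        return float(self.maturation_time)


@dataclass
class RunReport:
    """What a pipeline run produced, with per-stage flags."""

    outdir: Path
    files: dict[str, str]
    hill_maximum: dict[str, HillParams]
    hill_slope: dict[str, HillParams]
    flags: list[str]


def _hill_json(params_by_key: dict[str, HillParams]) -> str:
    payload = {
        key: {
            "H": p.H, "se_H": p.se_H, "k_I": p.k_I, "se_kI": p.se_kI,
            "n": p.n, "se_n": p.se_n, "form": p.form, "rss": p.rss,
            "converged": p.converged, "n_points": p.n_points,
            "flags": list(p.flags),
        }
        for key, p in params_by_key.items()
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def _plot_diagnostics(groups, channel, maturation, max_results, slope_fits, plots_dir) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .kinetics import rate_series

    written = []
    strains = sorted({g.strain for g in groups})
    for strain in strains:
        gs = [g for g in groups if g.strain == strain]
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.2))
        for g in gs:
            for s in g.series:
                rs = rate_series(s, channel, maturation)
                ax1.plot(rs.phi_times, rs.phi_h, lw=0.8, alpha=0.6)
                ax2.plot(rs.mu, rs.rho_h, ".", ms=2.5, alpha=0.4)
        for mr in max_results:
            if mr.strain != strain:
                continue
            ax1.plot(mr.t_max, [mr.phi_max_mean] * mr.t_max.size, "kv", ms=5)
        for sf in slope_fits:
            if sf.strain != strain:
                continue
            xs = np.linspace(0.0, max(sf.b, 0.0) + 0.8, 50)
            ax2.plot(xs, sf.slope * xs + sf.intercept, "-", lw=1)
        ax1.set(xlabel="time (h)", ylabel="phi_H = flu/OD", title=f"{strain}: reporter fraction")
        ax2.set(xlabel="mu (1/h)", ylabel="rho_H (flu/OD/h)", title="production vs growth")
        fig.tight_layout()
        out = plots_dir / f"diagnostics_{strain.replace('/', '_')}.png"
        fig.savefig(out, dpi=110)
        plt.close(fig)
        written.append(str(out))
    return written


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``. See module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flags: list[str] = []
    files: dict[str, str] = {}

    # --- input stage -------------------------------------------------------
    try:
        if config.simulation is not None:
            sim_cfg = SimConfig(**{**config.simulation, "seed": config.seed})
            if not config.concentrations:
                raise InsufficientDataError("simulation needs >= 1 concentration")
            titration = simulate_titration(sim_cfg, config.concentrations, allow_degenerate=True)
            groups, blanks = titration.groups, []
            titration.write(outdir / "simulated")
            files["simulated_data"] = str(outdir / "simulated" / "data.csv")
        else:
            groups, blanks = read_tidy_csv(config.data_csv, config.layout_csv, include_blanks=True)
        groups = blank_correct(groups, blanks, mode=config.blank_mode)
    except ExfracError as err:
        raise type(err)(f"[input] {err}") from err

    maturation = config.maturation_for(config.channel)

    # --- rates -------------------------------------------------------------
    rates = rates_table(groups, config.channel, maturation)
    rates.to_csv(outdir / "rates.csv", index=False)
    files["rates"] = str(outdir / "rates.csv")

    # --- per-condition estimates ------------------------------------------
    max_results, slope_fits = [], []
    for g in groups:
        cond = f"{g.strain}/{g.inducer}/{g.concentration}"
        try:
            max_results.append(find_phi_max(g, config.channel, config.window_h))
        except ExfracError as err:
            flags.append(f"max_method skipped for {cond}: {err}")
        try:
            slope_fits.append(
                slope_fit_group(
                    g, config.channel, maturation, alpha=config.alpha,
                    model=config.slope_model, min_points=config.min_points,
                    trim_rule=config.trim_rule,
                )
            )
        except ExfracError as err:
            flags.append(f"slope_method skipped for {cond}: {err}")
    max_method_table(max_results).to_csv(outdir / "max_method.csv", index=False)
    slope_method_table(slope_fits).to_csv(outdir / "slope_method.csv", index=False)
    files["max_method"] = str(outdir / "max_method.csv")
    files["slope_method"] = str(outdir / "slope_method.csv")

    # --- dose-response + Hill fits ----------------------------------------
    hill_max: dict[str, HillParams] = {}
    hill_slope: dict[str, HillParams] = {}
    comparisons = []
    keys = sorted({(g.strain, g.inducer) for g in groups})
    for strain, inducer in keys:
        key = f"{strain}/{inducer}"
        try:
            dr = max_dose_response([m for m in max_results if (m.strain, m.inducer) == (strain, inducer)])
            hill_max[key] = fit_hill(dr, form=config.hill_form)
        except ExfracError as err:
            flags.append(f"hill fit (maximum) skipped for {key}: {err}")
        try:
            dr = slope_dose_response([f for f in slope_fits if (f.strain, f.inducer) == (strain, inducer)])
            hill_slope[key] = fit_hill(dr, form=config.hill_form)
        except ExfracError as err:
            flags.append(f"hill fit (slope) skipped for {key}: {err}")
        if key in hill_max and key in hill_slope:
            cmp_rec = compare_methods(hill_max[key], hill_slope[key], strain=strain, inducer=inducer)
            tab = cmp_rec.table.copy()
            tab.insert(0, "inducer", inducer)
            tab.insert(0, "strain", strain)
            comparisons.append(tab)

    (outdir / "hill_maximum.json").write_text(_hill_json(hill_max))
    (outdir / "hill_slope.json").write_text(_hill_json(hill_slope))
    files["hill_maximum"] = str(outdir / "hill_maximum.json")
    files["hill_slope"] = str(outdir / "hill_slope.json")
    comp_df = (
        pd.concat(comparisons, ignore_index=True)
        if comparisons
        else pd.DataFrame(columns=["strain", "inducer", "parameter", "value_max", "value_slope", "abs_diff", "rel_diff", "z"])
    )
    comp_df.to_csv(outdir / "comparison.csv", index=False)
    files["comparison"] = str(outdir / "comparison.csv")

    # --- plots -------------------------------------------------------------
    if config.make_plots:
        plots_dir = outdir / "plots"
        plots_dir.mkdir(exist_ok=True)
        for i, p in enumerate(
            _plot_diagnostics(groups, config.channel, maturation, max_results, slope_fits, plots_dir)
        ):
            files[f"plot_{i}"] = p

    # --- manifest ----------------------------------------------------------
    cfg_dict = config.to_dict()
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "exfrac": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": files,
        "flags": flags,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files["manifest"] = str(outdir / "manifest.json")
    return RunReport(outdir=outdir, files=files, hill_maximum=hill_max, hill_slope=hill_slope, flags=flags)


def dose_response_to_csv(dr: DoseResponse, path: str | Path) -> None:
    """Write a dose-response table with its identifying columns."""
    tab = dr.table.copy()
    tab.insert(0, "method", dr.method)
    tab.insert(0, "inducer", dr.inducer)
    tab.insert(0, "strain", dr.strain)
    tab.to_csv(path, index=False)


def dose_response_from_csv(path: str | Path) -> DoseResponse:
    df = pd.read_csv(path)
    for col in ("strain", "inducer", "method", "concentration", "f_h", "variance", "n"):
        if col not in df.columns:
            raise ExfracError(f"dose-response file {path} is missing column {col!r}")
    return DoseResponse(
        strain=str(df["strain"].iloc[0]),
        inducer=str(df["inducer"].iloc[0]),
        method=str(df["method"].iloc[0]),
        table=df[[c for c in df.columns if c not in ("strain", "inducer", "method")]],
    )
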