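"""End-to-end nest simulation: geometry -> grid -> coupled thermal/metabolic
integration -> developmental outcomes -> artifacts on disk.

The metabolic heat flux depends on the clutch temperature, which the flux
itself modifies.  The coupling is resolved with a one-step lag: the flux
applied over hour t uses the simulated centre-egg temperature at hour t-1
(initially the steady-state field), so each hourly step remains a single
linear solve.  In validation mode a measured (or pseudo-observed) proxy
series can be supplied instead, which reproduces the field-driven workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash, config_to_yaml
from .geometry import ClutchLayout, NestGeometry, build_domain, logger_positions, pack_eggs
from .metabolism import (
    PRE_TERM_CUTOFF,
    assign_categories,
)
from .outcomes import predict_all, summary_to_json
from .series import hourly_index
from .synthetic import generate_boundaries
from .thermal import (
    FaceBC,
    SimulationGrid,
    SimulationResult,
    ThermalSolver,
    diel_damping_depth,
    extract_probe,
    nest_boundary_conditions,
    rasterize,
)

__all__ = ["NestRun", "build_model", "run_nest", "write_artifacts", "trimester_warming"]

ABOVE_DEPTH = 0.10  # m; depth of the above-nest forcing series


@dataclass
class NestRun:
    """Everything one simulation produced."""

    config: RunConfig
    geometry: NestGeometry
    layout: ClutchLayout
    result: SimulationResult
    schedule: pd.DataFrame  # per-egg applied wattage (W), hourly
    maturity: pd.Series  # proxy-driven clutch maturity (%)
    categories: dict[int, str]
    predictions: pd.DataFrame
    summary: dict
    above_series: pd.Series
    adjacent_series: pd.Series
    adjacent_depth: float
    probes: dict[str, pd.Series] = field(default_factory=dict)


def build_model(
    config: RunConfig,
) -> tuple[NestGeometry, ClutchLayout, SimulationGrid]:
    """Geometry, packed clutch and rasterised grid for a configuration."""
    g = config.geometry
    geometry = build_domain(
        g.nest_depth_m, g.clutch_size, g.egg_diameter_m, g.chamber()
    )
    layout = pack_eggs(geometry, g.clutch_size, seed=g.packing_seed)
    grid = rasterize(
        geometry,
        layout,
        config.materials.effective(),
        cell_size=config.solver.cell_size_m,
        top_depth=ABOVE_DEPTH,
    )
    return geometry, layout, grid


def run_nest(
    config: RunConfig,
    boundaries: dict[str, pd.Series] | None = None,
    proxy_series: pd.Series | None = None,
) -> NestRun:
    """Run one nest from config to predictions.

    ``boundaries`` may supply measured series {"above": ..., "adjacent": ...}
    (hourly, shared index); otherwise both are generated from the config's
    synthetic scenario at 10 cm and clutch-centre depth.  ``proxy_series``
    switches the metabolic feedback to a fixed external proxy (validation
    mode) instead of the lagged simulated centre-egg temperature.
    """
    geometry, layout, grid = build_model(config)
    base_pos, centre_pos, top_pos = logger_positions(geometry, layout)
    adjacent_depth = float(centre_pos[2])

    beach = config.materials.effective()["beach"]
    damping = diel_damping_depth(beach)

    if boundaries is None:
        series = generate_boundaries(config.scenario, [ABOVE_DEPTH, adjacent_depth])
        above = series[ABOVE_DEPTH].rename("above")
        adjacent = series[adjacent_depth].rename("adjacent")
    else:
        above = boundaries["above"].rename("above")
        adjacent = boundaries["adjacent"].rename("adjacent")
        if not above.index.equals(adjacent.index):
            raise ValueError("boundary series must share one time grid")
    times = above.index

    footprint = config.solver.footprint_radius_m or geometry.chamber.bulb_radius
    face_bcs = nest_boundary_conditions(
        grid, above, adjacent, adjacent_depth, damping, footprint
    )
    solver = ThermalSolver(
        grid,
        face_bcs,
        dt=3600.0 / config.solver.substeps,
        deposition=config.solver.deposition,
    )

    met = config.metabolism
    rate = met.rate()
    heat_curve = met.heat_curve()
    q10 = met.q10_params()
    categories = (
        assign_categories(layout.clutch_size, met.category_proportions, met.category_seed)
        if met.adjusted
        else ["hatched_or_pipped"] * layout.clutch_size
    )
    undeveloped = np.array([c == "undeveloped" for c in categories])
    pre_term = np.array([c == "pre_term_dead" for c in categories])

    # centre egg: the proxy for the clutch temperature driving the flux
    d_centre = np.sqrt(((layout.egg_centres - centre_pos) ** 2).sum(-1))
    centre_egg = int(np.argmin(d_centre))

    n_t = len(times)
    n_eggs = layout.clutch_size
    T = solver.steady(0.0)
    rec = np.empty((n_t, n_eggs))
    rec[0] = T[grid.egg_centre_cells]
    watts = np.zeros((n_t, n_eggs))
    maturity = np.zeros(n_t)
    ledger_rows = []
    snapshots: dict[int, np.ndarray] = {}
    snapshot_hours = set(config.solver.snapshot_hours)
    if 0 in snapshot_hours:
        snapshots[0] = T.reshape(grid.shape).copy()

    external_proxy = None
    if proxy_series is not None:
        if len(proxy_series) < n_t:
            raise ValueError("proxy series shorter than the simulation window")
        external_proxy = proxy_series.to_numpy(dtype=float)

    m = 0.0
    hatched = False
    substeps = config.solver.substeps
    for n in range(1, n_t):
        # proxy temperature for the flux over [n-1, n): lagged centre egg
        t_proxy = external_proxy[n - 1] if external_proxy is not None else rec[n - 1, centre_egg]
        if not hatched:
            m = min(100.0, m + float(rate.rate(t_proxy)))
        maturity[n] = m
        h_ref = float(heat_curve.at(m))
        if met.scaling == "dev_rate":
            factor = float(rate.rate(t_proxy) / rate.rate(q10.t_ref))
        else:
            factor = q10.q10 ** ((t_proxy - q10.t_ref) / 10.0)
        w = h_ref * factor / 1000.0  # mW -> W
        egg_w = np.full(n_eggs, w)
        egg_w[undeveloped] = 0.0
        if m > PRE_TERM_CUTOFF:
            egg_w[pre_term] = 0.0
        if hatched:
            egg_w[:] = 0.0
        watts[n - 1] = egg_w
        if m >= 100.0:
            hatched = True

        entry = {"storage_j": 0.0, "boundary_j": 0.0, "source_j": 0.0, "residual": 0.0}
        for s in range(substeps):
            t_index = (n - 1) + (s + 1) / substeps
            T, led = solver.step(T, t_index, egg_watts=egg_w)
            for key in ("storage_j", "boundary_j", "source_j"):
                entry[key] += led[key]
            entry["residual"] = max(entry["residual"], led["residual"])
        rec[n] = T[grid.egg_centre_cells]
        ledger_rows.append(entry)
        if n in snapshot_hours:
            snapshots[n] = T.reshape(grid.shape).copy()

    egg_temps = pd.DataFrame(rec, index=times, columns=range(n_eggs))
    ledger = pd.DataFrame(ledger_rows, index=times[1:])
    result = SimulationResult(egg_temps, ledger, layout=layout, snapshots=snapshots)
    schedule = pd.DataFrame(watts, index=times, columns=range(n_eggs))
    maturity_series = pd.Series(maturity, index=times, name="maturity")

    out = config.outcomes
    predictions, summary = predict_all(
        result,
        rate=rate,
        norm=out.norm(),
        logistic=out.logistic(),
        sand_series=adjacent,
        sex_mode=out.sex_mode,
    )
    summary["config_hash"] = config_hash(config)
    summary["clutch_size"] = n_eggs
    summary["categories"] = {c: categories.count(c) for c in set(categories)}

    probes = {
        "base": extract_probe(result, base_pos).rename("base"),
        "centre": extract_probe(result, centre_pos).rename("centre"),
        "top": extract_probe(result, top_pos).rename("top"),
    }
    return NestRun(
        config=config,
        geometry=geometry,
        layout=layout,
        result=result,
        schedule=schedule,
        maturity=maturity_series,
        categories=dict(enumerate(categories)),
        predictions=predictions,
        summary=summary,
        above_series=above,
        adjacent_series=adjacent,
        adjacent_depth=adjacent_depth,
        probes=probes,
    )


def trimester_warming(run: NestRun) -> dict[str, float]:
    """Metabolic warming per development trimester (C).

    Mean difference between the simulated centre-egg temperature and the
    adjacent-sand series (the field definition of metabolic heat), split by
    thirds of development from the clutch maturity trajectory.
    """
    centre = run.probes["centre"].to_numpy(dtype=float)
    adjacent = run.adjacent_series.to_numpy(dtype=float)
    m = run.maturity.to_numpy()
    diff = centre - adjacent
    out = {}
    for name, lo, hi in (
        ("first", 0.0, 100.0 / 3.0),
        ("second", 100.0 / 3.0, 200.0 / 3.0),
        ("third", 200.0 / 3.0, 100.0),
    ):
        sel = (m >= lo) & (m < hi) if hi < 100 else (m >= lo)
        out[name] = float(diff[sel].mean()) if sel.any() else float("nan")
    return out


def write_artifacts(run: NestRun, outdir) -> dict[str, Path]:
    """Persist a complete, reproducible artifact set.

    Writes the exact config (plus hash) next to per-egg temperatures, the
    flux schedule, boundary series, per-egg predictions and the summary.
    Outputs are formatted deterministically: the same config yields
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["config"] = outdir / "config.yaml"
    paths["config"].write_text(config_to_yaml(run.config))

    def long_format(frame: pd.DataFrame, value: str) -> pd.DataFrame:
        long = frame.stack().rename(value).reset_index()
        long.columns = ["timestamp", "egg_id", value]
        return long

    paths["egg_temps"] = outdir / "egg_temperatures.csv"
    long_format(run.result.egg_temps, "temp_c").to_csv(
        paths["egg_temps"], index=False, float_format="%.6f"
    )

    flux = long_format(run.schedule, "watts")
    flux["category"] = flux["egg_id"].map(run.categories)
    paths["flux"] = outdir / "flux_schedule.csv"
    flux.to_csv(paths["flux"], index=False, float_format="%.8f")

    bounds = pd.DataFrame(
        {
            "timestamp": run.above_series.index,
            "above_c": run.above_series.to_numpy(),
            "adjacent_c": run.adjacent_series.to_numpy(),
        }
    )
    paths["boundaries"] = outdir / "boundaries.csv"
    bounds.to_csv(paths["boundaries"], index=False, float_format="%.6f")

    paths["predictions"] = outdir / "predictions.csv"
    run.predictions.to_csv(paths["predictions"], float_format="%.6f")

    paths["summary"] = outdir / "summary.json"
    summary_to_json(run.summary, paths["summary"])

    paths["log"] = outdir / "run.log"
    paths["log"].write_text(
        "nestherm {version}\nconfig_hash {h}\nclutch_size {n}\nhours {t}\n".format(
            version=__version__,
            h=config_hash(run.config),
            n=run.layout.clutch_size,
            t=len(run.result.egg_temps),
        )
    )
    return paths
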