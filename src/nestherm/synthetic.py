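"""Synthetic boundary forcing and pseudo-observed logger series.

Field campaigns drive this model with two measured sand-temperature series
(10 cm below the surface above the nest, and adjacent sand at clutch-centre
depth).  This module replaces them with a generator carrying the same
statistical structure: a seasonal warming trend, a depth-damped and
phase-lagged diel cycle, and autocorrelated AR(1) noise, all reproducible
from a seed.  It can also run the forward model and overlay logger noise to
produce pseudo-"observed" series at the base/centre/top logger positions,
so the whole validation chain is testable without any field download.

What the generator does *not* emulate: rainfall and tidal events, storms
that add or remove sand above the nest, and any mean temperature gradient
with depth — the synthetic beach is seasonally warming but otherwise
statistically stationary with depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .materials import BEACH_SAND, sand_effective_properties
from .series import hourly_index
from .thermal import diel_damping_depth

__all__ = [
    "BoundaryScenario",
    "generate_boundaries",
    "make_reference_nest",
    "simulate_observed",
    "LOGGER_NOISE_SD",
]

# Logger accuracies: the base logger is the larger high-accuracy unit, the
# in-clutch and sand loggers are the small button loggers.
LOGGER_NOISE_SD = {
    "base": 0.2,
    "centre": 1.0,
    "top": 1.0,
    "adjacent": 1.0,
    "above": 1.0,
}


@dataclass(frozen=True)
class BoundaryScenario:
    """Parameters of the synthetic beach.

    ``diel_amplitude_c`` is the half-range of the diel cycle at the sand
    surface; it damps as exp(-z/D) with the damping depth D (defaulting to
    the value implied by the beach-sand thermal properties).  ``trend``
    captures seasonal warming over the ~55-day incubation.  Noise is AR(1)
    with stationary standard deviation ``noise_sd_c``.
    """

    duration_days: float = 55.0
    start: str = "2020-12-01"
    base_temp_c: float = 30.5
    trend_c_per_day: float = 0.055
    diel_amplitude_c: float = 3.5
    damping_depth_m: float | None = None
    noise_sd_c: float = 0.15
    ar1: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValueError("duration must be at least one day")
        if self.diel_amplitude_c < 0:
            raise ValueError("diel amplitude must be non-negative")
        if not -1 < self.ar1 < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")

    @property
    def n_hours(self) -> int:
        # inclusive endpoint: a 55-day scenario spans 55*24 + 1 hourly stamps
        return int(round(self.duration_days * 24)) + 1

    def resolved_damping_depth(self) -> float:
        if self.damping_depth_m is not None:
            return self.damping_depth_m
        return diel_damping_depth(sand_effective_properties(BEACH_SAND))


def generate_boundaries(
    scenario: BoundaryScenario, depths: list[float] | np.ndarray
) -> dict[float, pd.Series]:
    """Hourly temperature series at each requested depth (m below surface).

    T(z, t) = base + trend * t + A exp(-z/D) sin(omega t - z/D) + AR(1) noise.
    The phase lags with depth as the diel wave propagates downward.  Noise
    is drawn independently per depth from seeds spawned off the scenario
    seed, so adding a depth never perturbs the others.
    """
    d_depth = scenario.resolved_damping_depth()
    idx = hourly_index(scenario.start, scenario.n_hours)
    t_hours = np.arange(scenario.n_hours, dtype=float)
    omega = 2 * np.pi / 24.0
    out: dict[float, pd.Series] = {}
    for i, z in enumerate(depths):
        z = float(z)
        mean = scenario.base_temp_c + scenario.trend_c_per_day * t_hours / 24.0
        diel = (
            scenario.diel_amplitude_c
            * np.exp(-z / d_depth)
            * np.sin(omega * t_hours - z / d_depth)
        )
        rng = np.random.default_rng([scenario.seed, i])
        if scenario.noise_sd_c > 0:
            eps = rng.normal(
                scale=scenario.noise_sd_c * np.sqrt(1 - scenario.ar1**2),
                size=scenario.n_hours,
            )
            noise = np.empty(scenario.n_hours)
            noise[0] = rng.normal(scale=scenario.noise_sd_c)
            for t in range(1, scenario.n_hours):
                noise[t] = scenario.ar1 * noise[t - 1] + eps[t]
        else:
            noise = np.zeros(scenario.n_hours)
        out[z] = pd.Series(mean + diel + noise, index=idx, name=f"depth_{z:g}m")
    return out


def make_reference_nest(seed: int = 0):
    """The canonical simulation configuration: a 60 cm deep nest of 51 eggs
    of 46.7 mm diameter — the depth and clutch size of a typical flatback
    nest — with the published material properties, default physiology and
    the default synthetic beach."""
    from .config import RunConfig

    cfg = RunConfig()
    cfg = replace(
        cfg,
        geometry=replace(cfg.geometry, nest_depth_m=0.60, clutch_size=51,
                         egg_diameter_m=0.0467, packing_seed=seed),
        scenario=replace(cfg.scenario, seed=seed),
        metabolism=replace(cfg.metabolism, category_seed=seed),
    )
    return cfg


def simulate_observed(
    config=None,
    scenario: BoundaryScenario | None = None,
    logger_noise_sd: dict[str, float] | float | None = None,
    seed: int = 0,
):
    """Run the forward model and emit noisy pseudo-observed logger series.

    Returns ``(observed, run)`` where ``observed`` maps logger location
    (base/centre/top/adjacent/above) to an hourly series with independent
    Gaussian logger noise added (location-specific defaults mirror the two
    logger models' accuracies; pass 0 for noiseless series), and ``run`` is
    the full :class:`~nestherm.run.NestRun` the series were sampled from.
    """
    from .run import run_nest

    config = config or make_reference_nest(seed)
    if scenario is not None:
        config = replace(config, scenario=replace(
            config.scenario, **{k: getattr(scenario, k) for k in (
                "duration_days", "start", "base_temp_c", "trend_c_per_day",
                "diel_amplitude_c", "damping_depth_m", "noise_sd_c", "ar1", "seed",
            )}
        ))
    if logger_noise_sd is None:
        noise = dict(LOGGER_NOISE_SD)
    elif np.isscalar(logger_noise_sd):
        noise = {loc: float(logger_noise_sd) for loc in LOGGER_NOISE_SD}
    else:
        noise = {**LOGGER_NOISE_SD, **logger_noise_sd}

    run = run_nest(config)
    clean = {
        "base": run.probes["base"],
        "centre": run.probes["centre"],
        "top": run.probes["top"],
        "adjacent": run.adjacent_series,
        "above": run.above_series,
    }
    rng = np.random.default_rng([seed, 0xB0B])
    observed: dict[str, pd.Series] = {}
    for loc, series in clean.items():
        sd = noise.get(loc, 0.0)
        jitter = rng.normal(scale=sd, size=len(series)) if sd > 0 else 0.0
        observed[loc] = (series + jitter).rename(loc)
    return observed, run
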