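"""Embryonic development and metabolic heat fluxes.

Three-step flux chain, computed hourly from a clutch temperature proxy:

1. cumulative development: maturity (0-100%) integrates a temperature-
   dependent development-rate curve over the hourly temperature history;
2. reference heat: the metabolic heat an embryo of that maturity produces at
   the 29.5 C reference incubation temperature (mW per embryo);
3. temperature adjustment: the reference heat is scaled to the current
   temperature with a Q10 coefficient (or, optionally, with the ratio of
   development rates, which makes the coefficient itself temperature
   dependent).

The resulting per-egg hourly wattage is gated by the fate category assigned
to each egg: eggs that hatched or died full-term heat for their whole
incubation, eggs that died pre-term stop heating at two-thirds of
development, and undeveloped eggs never heat.

The development-rate and reference-heat equations are population-specific
fits; both are pluggable strategy objects whose defaults are calibrated to
the qualitative behaviour of a flatback clutch (development-rate peak
between 33 and 34 C, hatching in roughly 45-55 days at nest temperatures,
and a late-incubation central warming of about 3 C for a ~50-egg clutch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ClutchLayout

__all__ = [
    "DevRateCurve",
    "MetabolicHeatCurve",
    "Q10Params",
    "MORTALITY_CATEGORIES",
    "DEFAULT_CATEGORY_PROPORTIONS",
    "HeatFluxSchedule",
    "integrate_development",
    "reference_heat",
    "q10_adjust",
    "assign_categories",
    "build_schedule",
]

TSP_START = 100.0 / 3.0  # maturity bounds of the thermosensitive period (%)
TSP_END = 200.0 / 3.0
PRE_TERM_CUTOFF = TSP_END  # "terminated at two-thirds of development"

MORTALITY_CATEGORIES = (
    "hatched_or_pipped",
    "full_term_dead",
    "pre_term_dead",
    "undeveloped",
)

# Clutch fate proportions observed across the modelled nests (normalised).
DEFAULT_CATEGORY_PROPORTIONS = {
    "hatched_or_pipped": 0.378,
    "full_term_dead": 0.260,
    "pre_term_dead": 0.314,
    "undeveloped": 0.048,
}


@dataclass(frozen=True)
class DevRateCurve:
    """Thermal performance curve for development rate, in % per hour.

    An asymmetric Gaussian: slow rise over the ecological range below the
    optimum, sharp decline above it (development slows again at supra-optimal
    temperatures).  ``r_max`` is the peak rate in % per hour; ``t_opt`` the
    peak temperature; ``sigma_below``/``sigma_above`` the widths on either
    side in degrees C.
    """

    t_opt: float = 33.5
    r_max: float = 0.1  # %/h == 2.4 %/day at the optimum
    sigma_below: float = 8.0
    sigma_above: float = 2.5

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.sigma_below <= 0 or self.sigma_above <= 0:
            raise ValueError("curve parameters must be positive")

    def rate(self, temp_c: float | np.ndarray) -> np.ndarray:
        t = np.asarray(temp_c, dtype=float)
        sigma = np.where(t < self.t_opt, self.sigma_below, self.sigma_above)
        return self.r_max * np.exp(-0.5 * ((t - self.t_opt) / sigma) ** 2)

    __call__ = rate


@dataclass(frozen=True)
class MetabolicHeatCurve:
    """Reference metabolic heat (mW per embryo) versus maturity at 29.5 C.

    Exponential in maturity, anchored at zero for a fresh egg: heat rises
    slowly through the first half of development and steeply toward hatching,
    mirroring the growth of embryonic mass and metabolic rate.
    """

    h_max_mw: float = 65.0  # heat of a full-term embryo at 29.5 C
    gamma: float = 4.0  # exponential steepness over maturity

    def __post_init__(self) -> None:
        if self.h_max_mw <= 0 or self.gamma <= 0:
            raise ValueError("curve parameters must be positive")

    def at(self, maturity: float | np.ndarray) -> np.ndarray:
        m = np.asarray(maturity, dtype=float)
        if np.any((m < 0) | (m > 100)):
            raise ValueError("maturity must lie in [0, 100]")
        return self.h_max_mw * np.expm1(self.gamma * m / 100.0) / np.expm1(self.gamma)

    __call__ = at


@dataclass(frozen=True)
class Q10Params:
    """Q10 temperature scaling about the 29.5 C reference."""

    q10: float = 2.0
    t_ref: float = 29.5

    def __post_init__(self) -> None:
        if self.q10 <= 1:
            raise ValueError("Q10 must exceed 1")


def integrate_development(
    t_series: pd.Series, rate: DevRateCurve
) -> tuple[pd.Series, int | None]:
    """Hourly maturity trajectory and the hatch hour.

    maturity(t) = min(100, sum_i r(T_i) * 1 h); the hatch hour is the first
    stamp at which maturity reaches 100 (None if it never does).  The series
    must be hourly and finite.
    """
    from .series import ensure_hourly

    ensure_hourly(t_series)
    vals = t_series.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("temperature series contains non-finite values")
    increments = rate.rate(vals)
    maturity = np.minimum(np.cumsum(increments), 100.0)
    hatched = np.flatnonzero(maturity >= 100.0)
    hatch_hour = int(hatched[0]) if len(hatched) else None
    return pd.Series(maturity, index=t_series.index, name="maturity"), hatch_hour


def reference_heat(maturity, curve: MetabolicHeatCurve | None = None) -> np.ndarray:
    """Metabolic heat (mW per embryo) at the 29.5 C reference incubation."""
    return (curve or MetabolicHeatCurve()).at(maturity)


def q10_adjust(h_ref_mw, temp_c, params: Q10Params | None = None) -> np.ndarray:
    """Scale a reference heat to temperature T: h = h_ref * Q10^((T-Tref)/10)."""
    params = params or Q10Params()
    h = np.asarray(h_ref_mw, dtype=float)
    if np.any(h < 0):
        raise ValueError("reference heat must be non-negative")
    return h * params.q10 ** ((np.asarray(temp_c, dtype=float) - params.t_ref) / 10.0)


def dev_rate_scaling(rate: DevRateCurve, temp_c, t_ref: float = 29.5) -> np.ndarray:
    """Temperature scaling factor derived from the development-rate curve
    itself (ratio form): a Q10 that follows the expected development rates at
    each temperature, including the decline above the optimum."""
    return rate.rate(temp_c) / rate.rate(t_ref)


def assign_categories(
    clutch_size: int,
    proportions: dict[str, float] | None = None,
    seed: int = 0,
) -> list[str]:
    """Random egg-fate assignment with fixed category counts.

    Counts are the proportions rounded largest-remainder to sum to the
    clutch size; positions within the clutch are shuffled with the seed.
    """
    props = dict(DEFAULT_CATEGORY_PROPORTIONS if proportions is None else proportions)
    unknown = set(props) - set(MORTALITY_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    total = sum(props.values())
    if total <= 0:
        raise ValueError("category proportions must sum to a positive value")
    shares = {c: props.get(c, 0.0) / total * clutch_size for c in MORTALITY_CATEGORIES}
    counts = {c: int(np.floor(v)) for c, v in shares.items()}
    remainder = clutch_size - sum(counts.values())
    by_frac = sorted(
        MORTALITY_CATEGORIES, key=lambda c: shares[c] - counts[c], reverse=True
    )
    for c in by_frac[:remainder]:
        counts[c] += 1
    labels = [c for c in MORTALITY_CATEGORIES for _ in range(counts[c])]
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return labels


@dataclass
class HeatFluxSchedule:
    """Per-egg hourly heat sources in W, with the gating metadata.

    ``watts`` rows are hourly stamps, columns egg ids.  ``categories`` maps
    egg id to its fate; ``cutoff_hours`` to the hour its flux was terminated
    (None when the flux ran to the end of the window).
    """

    watts: pd.DataFrame
    categories: dict[int, str] = field(default_factory=dict)
    cutoff_hours: dict[int, int | None] = field(default_factory=dict)
    maturity: pd.Series | None = None
    hatch_hour: int | None = None

    def __post_init__(self) -> None:
        if (self.watts.to_numpy() < 0).any():
            raise ValueError("heat fluxes must be non-negative")

    def total_energy_j(self) -> float:
        return float(self.watts.to_numpy().sum() * 3600.0)

    def to_csv(self, path) -> None:
        long = self.watts.stack().rename("watts").reset_index()
        long.columns = ["timestamp", "egg_id", "watts"]
        long["category"] = long["egg_id"].map(self.categories)
        long.to_csv(path, index=False, float_format="%.8f")


def build_schedule(
    t_proxy_series: pd.Series,
    clutch: ClutchLayout | int,
    categories: list[str] | None = None,
    rate: DevRateCurve | None = None,
    heat_curve: MetabolicHeatCurve | None = None,
    q10: Q10Params | None = None,
    scaling: str = "q10",
) -> HeatFluxSchedule:
    """Hourly per-egg heat-flux schedule from a clutch temperature proxy.

    All eggs share the maturity trajectory and unit flux computed from the
    proxy series (one standardised flux per nest); per-egg gating
    applies the fate categories: undeveloped eggs never heat, pre-term dead
    eggs stop at two-thirds of development, hatched and full-term eggs heat
    until the hatch hour.  With ``categories=None`` all eggs are treated as
    viable (the "unadjusted" model).
    """
    rate = rate or DevRateCurve()
    heat_curve = heat_curve or MetabolicHeatCurve()
    q10 = q10 or Q10Params()
    n_eggs = clutch.clutch_size if isinstance(clutch, ClutchLayout) else int(clutch)
    if categories is not None and len(categories) != n_eggs:
        raise ValueError("need one category per egg")

    maturity, hatch_hour = integrate_development(t_proxy_series, rate)
    h_ref = heat_curve.at(maturity.to_numpy())
    temps = t_proxy_series.to_numpy(dtype=float)
    if scaling == "q10":
        h_mw = q10_adjust(h_ref, temps, q10)
    elif scaling == "dev_rate":
        h_mw = h_ref * dev_rate_scaling(rate, temps, q10.t_ref)
    else:
        raise ValueError("scaling must be 'q10' or 'dev_rate'")
    base_w = h_mw / 1000.0
    if hatch_hour is not None:
        base_w = base_w.copy()
        base_w[hatch_hour:] = 0.0

    n_t = len(t_proxy_series)
    watts = np.tile(base_w[:, None], (1, n_eggs))
    cats = {e: "hatched_or_pipped" for e in range(n_eggs)}
    cutoffs: dict[int, int | None] = {e: hatch_hour for e in range(n_eggs)}
    if categories is not None:
        m = maturity.to_numpy()
        pre_term_idx = np.flatnonzero(m > PRE_TERM_CUTOFF)
        pre_term_hour = int(pre_term_idx[0]) if len(pre_term_idx) else None
        for e, cat in enumerate(categories):
            cats[e] = cat
            if cat == "undeveloped":
                watts[:, e] = 0.0
                cutoffs[e] = 0
            elif cat == "pre_term_dead" and pre_term_hour is not None:
                watts[pre_term_hour:, e] = 0.0
                cutoffs[e] = pre_term_hour

    frame = pd.DataFrame(watts, index=t_proxy_series.index, columns=range(n_eggs))
    return HeatFluxSchedule(
        frame, cats, cutoffs, maturity=maturity, hatch_hour=hatch_hour
    )
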