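"""Developmental outcomes from incubation temperature histories.

Three predictions per embryo:

* incubation duration — the hour at which integrated development reaches
  100%, in days;
* sex — the probability of developing as female under a Hill-type
  temperature-dependent sex determination (TSD) reaction norm evaluated over
  the thermosensitive period (TSP, the middle third of development);
* hatching success — a logistic in mean incubation temperature with its
  inflection at 32.7 C, above which embryonic mortality rises steeply.

The Hill reaction norm is placed on the log-temperature scale: the logit of
the male proportion is linear in ln T with slope 1/S, crossing 1/2 at the
pivotal temperature P.  With the flatback parameters P = 30.3 and S = -0.01
this reproduces the published transitional range of temperatures (TRT,
29.4-31.2 C at the 5%/95% levels); the same parameters on a linear
temperature scale do not, which is why the log scale is the default and only
form implemented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metabolism import DevRateCurve, TSP_END, TSP_START, integrate_development

__all__ = [
    "TSDReactionNorm",
    "HatchLogistic",
    "OutcomePrediction",
    "female_probability",
    "trt_limits",
    "tsp_mean_temperature",
    "hatch_probability",
    "predict_egg",
    "predict_all",
]


@dataclass(frozen=True)
class TSDReactionNorm:
    """Hill TSD reaction norm: pivotal temperature P (C) and signed shape S.

    S < 0 makes warmer temperatures female-producing (the sea-turtle
    pattern); |S| controls the width of the transitional range.
    """

    pivotal_temp: float = 30.3
    shape: float = -0.01

    def __post_init__(self) -> None:
        if self.shape == 0:
            raise ValueError("shape S must be non-zero")
        if self.pivotal_temp <= 0:
            raise ValueError("pivotal temperature must be positive (Celsius)")


@dataclass(frozen=True)
class HatchLogistic:
    """Hatching-success logistic: p = 1 / (1 + exp(slope * (T - inflection))).

    The 32.7 C inflection is the critical temperature above which sea-turtle
    hatchling mortality increases sharply; the slope is a configurable
    steepness (per degree C) calibrated against the multispecies
    temperature-mortality relationship.
    """

    inflection: float = 32.7
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")


def female_probability(
    temp_c: float | np.ndarray, norm: TSDReactionNorm | None = None
) -> np.ndarray:
    """Probability of developing as female at constant temperature T.

    p_male = 1 / (1 + exp((1/S) (ln P - ln T))); p_female = 1 - p_male.
    Strictly increasing in T for S < 0, with p_female(P) = 1/2.
    """
    norm = norm or TSDReactionNorm()
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Celsius scale)")
    logit = (np.log(norm.pivotal_temp) - np.log(t)) / norm.shape
    p_male = 1.0 / (1.0 + np.exp(logit))
    return 1.0 - p_male


def trt_limits(
    norm: TSDReactionNorm | None = None, level: float = 0.05
) -> tuple[float, float]:
    """Transitional range of temperatures at the given tail level.

    Solves p_female = level and 1 - level in closed form:
    T = P exp(+/- S ln((1-level)/level)).  For S -> 0 both limits collapse
    to the pivotal temperature (step-function reaction norm).
    """
    norm = norm or TSDReactionNorm()
    if not 0 < level < 0.5:
        raise ValueError("level must lie in (0, 0.5)")
    span = abs(norm.shape) * np.log((1 - level) / level)
    t_low = norm.pivotal_temp * np.exp(-span)
    t_high = norm.pivotal_temp * np.exp(span)
    return float(t_low), float(t_high)


def tsp_mean_temperature(
    t_series: pd.Series, maturity: pd.Series
) -> tuple[float, bool]:
    """Mean temperature over the thermosensitive period.

    The TSP covers maturity in [33.3%, 66.7%).  Returns (mean, complete);
    ``complete`` is False when development stopped inside the TSP, in which
    case the mean covers the partial window.  Raises if the embryo never
    entered the TSP.
    """
    m = maturity.to_numpy(dtype=float)
    in_tsp = (m >= TSP_START) & (m < TSP_END)
    if not in_tsp.any():
        raise ValueError("embryo never entered the thermosensitive period")
    mean = float(t_series.to_numpy(dtype=float)[in_tsp].mean())
    complete = bool(m.max() >= TSP_END)
    return mean, complete


def hatch_probability(
    mean_temp_c: float | np.ndarray, logistic: HatchLogistic | None = None
) -> np.ndarray:
    """Hatching success from mean incubation temperature."""
    logistic = logistic or HatchLogistic()
    t = np.asarray(mean_temp_c, dtype=float)
    return 1.0 / (1.0 + np.exp(logistic.slope * (t - logistic.inflection)))


@dataclass
class OutcomePrediction:
    """Per-embryo prediction: duration (days, NaN when unhatched), female
    and hatch probabilities, and the temperature summaries behind them."""

    egg_id: int
    duration_days: float
    p_female: float
    p_hatch: float
    tsp_mean_c: float
    mean_c: float
    tsp_complete: bool = True

    def __post_init__(self) -> None:
        for p in (self.p_female, self.p_hatch):
            if not np.isnan(p) and not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def predict_egg(
    t_series: pd.Series,
    egg_id: int = 0,
    rate: DevRateCurve | None = None,
    norm: TSDReactionNorm | None = None,
    logistic: HatchLogistic | None = None,
    sex_mode: str = "tsp_mean",
) -> OutcomePrediction:
    """Outcome prediction for one temperature history.

    ``sex_mode`` selects how the reaction norm is aggregated over the TSP:
    "tsp_mean" applies the norm to the mean TSP temperature; "hourly"
    averages the hourly female probabilities over the TSP (a development
    model may do either; they differ when the TSP spans the steep part of
    the norm).
    """
    rate = rate or DevRateCurve()
    norm = norm or TSDReactionNorm()
    logistic = logistic or HatchLogistic()
    maturity, hatch_hour = integrate_development(t_series, rate)

    try:
        tsp_mean, complete = tsp_mean_temperature(t_series, maturity)
    except ValueError:
        # window too short for the embryo to reach the TSP: no sex prediction
        tsp_mean, complete = float("nan"), False
    if np.isnan(tsp_mean):
        p_f = float("nan")
    elif sex_mode == "tsp_mean":
        p_f = float(female_probability(tsp_mean, norm))
    elif sex_mode == "hourly":
        m = maturity.to_numpy()
        sel = (m >= TSP_START) & (m < TSP_END)
        p_f = float(female_probability(t_series.to_numpy()[sel], norm).mean())
    else:
        raise ValueError("sex_mode must be 'tsp_mean' or 'hourly'")

    if hatch_hour is not None:
        duration = hatch_hour / 24.0
        mean_c = float(t_series.iloc[: hatch_hour + 1].mean())
    else:
        duration = float("nan")
        mean_c = float(t_series.mean())
    p_h = float(hatch_probability(mean_c, logistic))
    return OutcomePrediction(
        egg_id, duration, p_f, p_h, tsp_mean, mean_c, tsp_complete=complete
    )


def predict_all(
    result,
    rate: DevRateCurve | None = None,
    norm: TSDReactionNorm | None = None,
    logistic: HatchLogistic | None = None,
    sand_series: pd.Series | None = None,
    sex_mode: str = "tsp_mean",
    corrections: tuple[float, ...] = (0.5, 1.0, 1.5),
) -> tuple[pd.DataFrame, dict]:
    """Predictions for every egg of a simulation, plus a clutch summary.

    ``result`` is a :class:`~nestherm.thermal.SimulationResult` (anything
    with an ``egg_temps`` DataFrame works).  When ``sand_series`` is given
    the summary also carries single predictions from the sand proxy and its
    +0.5/+1.0/+1.5 C corrected variants, the conventional alternatives to
    modelling the clutch explicitly.
    """
    rate = rate or DevRateCurve()
    norm = norm or TSDReactionNorm()
    logistic = logistic or HatchLogistic()
    rows = []
    for egg in result.egg_temps.columns:
        pred = predict_egg(
            result.egg_temps[egg], int(egg), rate, norm, logistic, sex_mode
        )
        rows.append(vars(pred))
    table = pd.DataFrame(rows).set_index("egg_id")

    durations = table["duration_days"].dropna()
    summary: dict = {
        "n_eggs": int(len(table)),
        "n_hatched": int(durations.size),
        "mean_duration_days": float(durations.mean()) if durations.size else None,
        "duration_range_days": (
            [float(durations.min()), float(durations.max())] if durations.size else None
        ),
        "mean_p_female": float(table["p_female"].mean()),
        "mean_p_hatch": float(table["p_hatch"].mean()),
        "p_hatch_range": [float(table["p_hatch"].min()), float(table["p_hatch"].max())],
        "mean_tsp_c": float(table["tsp_mean_c"].mean()),
        "mean_incubation_c": float(table["mean_c"].mean()),
    }

    if sand_series is not None:
        proxies = {"sand": sand_series}
        for dc in corrections:
            proxies[f"sand+{dc:g}"] = sand_series + dc
        for name, series in proxies.items():
            pred = predict_egg(series, -1, rate, norm, logistic, sex_mode)
            summary[name] = {
                "duration_days": pred.duration_days,
                "p_female": pred.p_female,
                "p_hatch": pred.p_hatch,
                "tsp_mean_c": pred.tsp_mean_c,
            }
    return table, summary


def summary_to_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
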