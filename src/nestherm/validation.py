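"""Model-performance metrics against observed logger series.

Predicted and observed series are aligned on the eight-hourly stamps the
field loggers share (00:00, 08:00, 16:00) and compared with RMSE, R^2, mean
error (ME, positive when the model runs warm) and mean absolute error (MAE).
R^2 is the squared Pearson correlation between observed and predicted by
default; the 1 - SSE/SST definition (which differs off the identity line)
is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PairedSeries", "align", "metrics", "metrics_table"]


@dataclass
class PairedSeries:
    """Aligned observed/predicted pairs with their shared timestamps."""

    timestamps: pd.DatetimeIndex
    observed: np.ndarray
    predicted: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (len(self.timestamps) == len(self.observed) == len(self.predicted)):
            raise ValueError("paired series must have equal lengths")

    def __len__(self) -> int:
        return len(self.timestamps)


def align(
    observed: pd.Series, predicted: pd.Series, cadence_hours: int = 8
) -> PairedSeries:
    """Inner-join two series on the shared ``cadence_hours`` stamps.

    Only stamps at whole multiples of the cadence from midnight are kept
    (00:00/08:00/16:00 for the default); stamps present in one series but
    not the other are dropped with a warning count.  An empty intersection
    raises.
    """
    def on_grid(s: pd.Series) -> pd.Series:
        idx = s.index
        mask = (idx.hour % cadence_hours == 0) & (idx.minute == 0) & (idx.second == 0)
        return s[mask]

    obs = on_grid(observed)
    pred = on_grid(predicted)
    common = obs.index.intersection(pred.index)
    if len(common) == 0:
        raise ValueError("no shared timestamps on the comparison grid")
    n_dropped = (len(obs) - len(common)) + (len(pred) - len(common))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} unmatched stamps", stacklevel=2)
    return PairedSeries(
        common,
        obs.loc[common].to_numpy(dtype=float),
        pred.loc[common].to_numpy(dtype=float),
        n_dropped=n_dropped,
    )


def metrics(pairs: PairedSeries, r2_definition: str = "pearson") -> dict[str, float]:
    """RMSE, R^2, ME and MAE of predicted against observed.

    ME = mean(pred - obs), so a positive ME means the model runs warmer than
    the observations.  R^2 is reported as NaN when either series has zero
    variance (correlation undefined).
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    err = pairs.predicted - pairs.observed
    rmse = float(np.sqrt(np.mean(err**2)))
    me = float(np.mean(err))
    mae = float(np.mean(np.abs(err)))
    so, sp = np.std(pairs.observed), np.std(pairs.predicted)
    if so == 0 or sp == 0:
        warnings.warn("zero variance: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    elif r2_definition == "pearson":
        r = np.corrcoef(pairs.observed, pairs.predicted)[0, 1]
        r2 = float(r * r)
    elif r2_definition == "sse":
        sst = float(np.sum((pairs.observed - pairs.observed.mean()) ** 2))
        r2 = float(1.0 - np.sum(err**2) / sst)
    else:
        raise ValueError("r2_definition must be 'pearson' or 'sse'")
    return {"rmse": rmse, "r2": r2, "me": me, "mae": mae}


def metrics_table(
    observed: dict[str, pd.Series],
    predicted: dict[str, pd.Series],
    cadence_hours: int = 8,
) -> pd.DataFrame:
    """Per-location metrics table (rows: locations such as base/centre/top)."""
    rows = {}
    for loc in observed:
        if loc not in predicted:
            raise KeyError(f"no prediction for location '{loc}'")
        rows[loc] = metrics(align(observed[loc], predicted[loc], cadence_hours))
    return pd.DataFrame(rows).T[["rmse", "r2", "mae", "me"]]
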