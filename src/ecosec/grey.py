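"""GM(1,1) grey prediction of risk trajectories.

The grey model of first order in one variable forecasts a short positive
series x0(1..n) without distributional assumptions: cumulate the series
(AGO), form the background values z1(k) = a_bg*x1(k) + (1-a_bg)*x1(k-1)
(a_bg = 0.5, the adjacent-mean convention), solve the grey differential
equation x0(k) + a*z1(k) = b for the development coefficient a and grey
input b by least squares, forecast the accumulated series

    x1(t+1) = (x0(1) - b/a) e^{-a t} + b/a

and difference back (IAGO).  The fitted value at k=1 equals x0(1) exactly.
Applied per fishnet cell to project future risk values and grades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import DEFAULT_GRADE_SCHEME, GradeScheme, RiskGrid, classify_grades

__all__ = [
    "GM11Model",
    "FitQuality",
    "fit_gm11",
    "predict_gm11",
    "fit_quality",
    "forecast_risk_grid",
]

logger = logging.getLogger(__name__)

# below this |a| the exponential solution is numerically meaningless and
# the model degenerates to linear accumulation x1(t+1) = x0(1) + b*t
_A_EPS = 1e-12


@dataclass(frozen=True)
class GM11Model:
    """Fitted GM(1,1): development coefficient a, grey input b, anchor x0(1)."""

    a: float
    b: float
    x0_1: float
    alpha_bg: float
    fitted: np.ndarray  # original-scale fitted series, length n_obs
    n_obs: int


@dataclass(frozen=True)
class FitQuality:
    """R^2 and RMSE of fitted vs observed; R^2 is None for constant data."""

    r2: float | None
    rmse: float


def fit_gm11(series, alpha_bg: float = 0.5) -> GM11Model:
    """Fit GM(1,1) to a positive series of length >= 4.

    (a, b) solve the least-squares system x0(k) = -a*z1(k) + b over
    k = 2..n, where z1 is the weighted adjacent mean of the accumulated
    series with background coefficient ``alpha_bg``.
    """
    x0 = np.asarray(series, dtype=float)
    if x0.ndim != 1 or x0.size < 4:
        raise ValueError("GM(1,1) needs a 1-D series of length >= 4")
    if (x0 <= 0).any():
        raise ValueError("GM(1,1) requires a strictly positive series")
    if not 0.0 < alpha_bg < 1.0:
        raise ValueError("background coefficient must lie in (0, 1)")
    x1 = np.cumsum(x0)
    z1 = alpha_bg * x1[1:] + (1.0 - alpha_bg) * x1[:-1]
    # design matrix of x0(k) + a z1(k) = b  =>  x0 = [-z1, 1] @ [a, b]
    B = np.column_stack([-z1, np.ones(z1.size)])
    (a, b), *_ = np.linalg.lstsq(B, x0[1:], rcond=None)
    fitted = _reconstruct(float(a), float(b), float(x0[0]), x0.size)
    return GM11Model(float(a), float(b), float(x0[0]), alpha_bg, fitted, x0.size)


def _accumulated(a: float, b: float, x0_1: float, t: np.ndarray) -> np.ndarray:
    """x1(t+1) for t = 0, 1, 2, ... (t=0 gives x1(1) = x0(1))."""
    if abs(a) < _A_EPS:
        return x0_1 + b * t
    return (x0_1 - b / a) * np.exp(-a * t) + b / a


def _reconstruct(a: float, b: float, x0_1: float, n: int) -> np.ndarray:
    t = np.arange(n, dtype=float)
    x1_hat = _accumulated(a, b, x0_1, t)
    out = np.empty(n)
    out[0] = x0_1  # anchor: fitted k=1 equals the first observation
    out[1:] = np.diff(x1_hat)
    return out


def predict_gm11(model: GM11Model, horizon: int) -> np.ndarray:
    """Original-scale forecasts for ``horizon`` steps beyond the series."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    n = model.n_obs
    t = np.arange(n - 1, n + horizon, dtype=float)
    x1_hat = _accumulated(model.a, model.b, model.x0_1, t)
    return np.diff(x1_hat)


def fit_quality(observed, fitted) -> FitQuality:
    """RMSE and R^2 = 1 - SSres/SStot of a fitted series."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValueError("observed and fitted must be equal-length, size >= 2")
    resid = obs - fit
    rmse = float(np.sqrt(np.mean(resid**2)))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = None if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    return FitQuality(r2, rmse)


def forecast_risk_grid(
    grids: list[RiskGrid],
    horizons: list[int],
    scheme: GradeScheme = DEFAULT_GRADE_SCHEME,
    alpha_bg: float = 0.5,
) -> tuple[list[RiskGrid], pd.DataFrame]:
    """Forecast future risk grids by an independent GM(1,1) per cell.

    Parameters
    ----------
    grids
        Risk grids of >= 4 epochs on one shared fishnet, chronological.
    horizons
        Steps ahead to report (e.g. [1, 2] for the next two epochs).

    Returns
    -------
    forecast grids (one per horizon, grades classified with ``scheme``)
    and a per-cell diagnostics table (a, b, R^2, RMSE, skipped flag).
    """
    if len(grids) < 4:
        raise ValueError("grey forecasting needs at least 4 epochs")
    net = grids[0].net
    for g in grids[1:]:
        if (len(g.net) != len(net)
                or not np.array_equal(g.net.rows, net.rows)
                or not np.array_equal(g.net.cols, net.cols)):
            raise ValueError("all epochs must share one fishnet")
    series = np.column_stack([g.eri for g in grids])  # (cells, epochs)
    max_h = max(horizons)
    n_cells = series.shape[0]
    forecasts = np.full((n_cells, max_h), np.nan)
    diag_rows = []
    for i in range(n_cells):
        s = series[i]
        if (s <= 0).any():
            logger.warning("cell %d has non-positive risk; skipped", i)
            diag_rows.append({"cell": i, "a": np.nan, "b": np.nan,
                              "r2": np.nan, "rmse": np.nan, "skipped": True})
            forecasts[i] = s[-1]  # carried forward so the grid stays complete
            continue
        model = fit_gm11(s, alpha_bg=alpha_bg)
        q = fit_quality(s, model.fitted)
        forecasts[i] = predict_gm11(model, max_h)
        diag_rows.append({"cell": i, "a": model.a, "b": model.b,
                          "r2": np.nan if q.r2 is None else q.r2,
                          "rmse": q.rmse, "skipped": False})
    out = []
    for h in horizons:
        eri_h = np.clip(forecasts[:, h - 1], 0.0, scheme.upper)
        out.append(RiskGrid(net, eri_h, classify_grades(eri_h, scheme),
                            epoch=f"+{h}"))
    return out, pd.DataFrame(diag_rows)
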