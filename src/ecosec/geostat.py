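"""Semivariogram estimation, model fitting and ordinary kriging.

The security surface is interpolated from the fishnet cell-center risk
values by ordinary kriging.  The empirical semivariogram

    gamma(h) = 1/(2 N(h)) * sum [Z(x_i) - Z(x_i + h)]^2

is binned by pair separation, a spherical or exponential model
(nugget C0, partial sill C, range A) is fitted by pair-count-weighted least
squares, and the kriging system with a Lagrange multiplier (weights sum to
1) yields predictions and kriging variance.  The exponential range is
reported as the practical range (95% of the sill), matching common GIS
software conventions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .synthetic import PointSamples, variogram_value

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "empirical_variogram",
    "fit_variogram_model",
    "nugget_sill_ratio",
    "ordinary_kriging",
]

logger = logging.getLogger(__name__)


@dataclass
class EmpiricalVariogram:
    """Binned sample semivariogram: lag centers, gamma(h), pair counts."""

    lags: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    reliable: bool = True

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag centers must be strictly increasing")
        if np.any(self.counts < 1):
            raise ValueError("reported bins need at least one pair")


@dataclass(frozen=True)
class VariogramModel:
    """Fitted isotropic variogram model."""

    family: str
    nugget: float
    partial_sill: float
    range_: float

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def nugget_sill_ratio(self) -> float:
        return self.nugget / self.sill

    def __call__(self, h: np.ndarray) -> np.ndarray:
        return variogram_value(self.family, h, self.nugget, self.partial_sill,
                               self.range_)


def empirical_variogram(
    points: PointSamples,
    n_lags: int = 12,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Bin squared value differences by pair separation.

    ``max_dist`` defaults to half the maximum pairwise distance; pairs
    beyond it are excluded.  Empty bins are omitted.  Fewer than 30 points
    triggers a warning and flags the result unreliable rather than failing.
    """
    n = len(points)
    reliable = True
    if n < 30:
        warnings.warn(f"only {n} points: variogram flagged unreliable", stacklevel=2)
        reliable = False
    coords = np.column_stack([points.x, points.y])
    d = cdist(coords, coords)
    iu = np.triu_indices(n, k=1)
    dist = d[iu]
    if max_dist is None:
        max_dist = dist.max() / 2.0
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    sq = (points.values[:, None] - points.values[None, :]) ** 2
    sqd = sq[iu]
    keep = dist <= max_dist
    dist, sqd = dist[keep], sqd[keep]
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    # (lower, upper] bins: a pair exactly on an edge joins the lower bin
    which = np.clip(np.digitize(dist, edges, right=True) - 1, 0, n_lags - 1)
    counts = np.bincount(which, minlength=n_lags)
    sums = np.bincount(which, weights=sqd, minlength=n_lags)
    nonempty = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    gamma = sums[nonempty] / (2.0 * counts[nonempty])
    return EmpiricalVariogram(centers[nonempty], gamma, counts[nonempty],
                              reliable=reliable)


def fit_variogram_model(
    emp: EmpiricalVariogram,
    family: str = "spherical",
) -> VariogramModel:
    """Fit (nugget, partial sill, range) by pair-count-weighted least squares.

    Bounded trust-region least squares from five deterministic starting
    points (combinations of low/high nugget share and short/long range) to
    dodge local minima; the best converged fit wins.
    """
    if emp.lags.size < 4:
        raise ValueError("need at least 4 variogram bins to fit a model")
    h, g, w = emp.lags, emp.gamma, np.sqrt(emp.counts.astype(float))
    g_max = max(g.max(), 1e-30)
    h_max = h.max()

    def residuals(p):
        nugget, psill, rng = p
        return w * (variogram_value(family, h, nugget, psill, rng) - g)

    starts = [
        (0.0, g_max, h_max / 2),
        (0.1 * g_max, 0.9 * g_max, h_max / 3),
        (0.5 * g_max, 0.5 * g_max, h_max / 2),
        (0.0, g_max, h_max),
        (0.25 * g_max, 0.75 * g_max, h_max / 5),
    ]
    lower = np.array([0.0, 0.0, 1e-12 * h_max])
    upper = np.array([2 * g_max, 4 * g_max, 10 * h_max])
    best = None
    for p0 in starts:
        try:
            sol = least_squares(residuals, np.clip(p0, lower, upper),
                                bounds=(lower, upper), method="trf")
        except Exception:  # singular Jacobian etc.: try the next start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(
            f"variogram fit failed for family {family!r}: "
            + (best.message if best is not None else "no start converged")
        )
    nugget, psill, rng = best.x
    return VariogramModel(family, float(nugget), float(psill), float(rng))


def nugget_sill_ratio(model: VariogramModel | None = None,
                      nugget: float | None = None,
                      sill: float | None = None) -> float:
    """Nugget-to-sill ratio as a percentage, 100 * C0 / (C0 + C).

    Ratios under about 25% indicate strong spatial structure, which is what
    justifies kriging the risk surface.  Accepts either a fitted model or
    raw (nugget, sill) values.
    """
    if model is not None:
        nugget, sill = model.nugget, model.sill
    if sill is None or nugget is None:
        raise ValueError("give either a model or both nugget and sill")
    if sill <= 0:
        raise ValueError("sill must be positive")
    return 100.0 * nugget / sill


def _dedupe(points: PointSamples) -> PointSamples:
    coords = np.column_stack([points.x, points.y])
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    if uniq.shape[0] == coords.shape[0]:
        return points
    logger.warning("duplicate sample locations: averaging %d -> %d points",
                   coords.shape[0], uniq.shape[0])
    vals = np.bincount(inv, weights=points.values) / np.bincount(inv)
    return PointSamples(uniq[:, 0], uniq[:, 1], vals)


def ordinary_kriging(
    model: VariogramModel,
    points: PointSamples,
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging at target locations; global neighborhood.

    Solves the standard system

        [Gamma 1] [lambda]   [gamma0]
        [1'    0] [mu    ] = [1     ]

    for every target, where Gamma holds model semivariances between data
    points.  Returns ``(predictions, kriging_variance)``.  Duplicate sample
    locations are averaged first (they would make the system singular).

    Parameters
    ----------
    targets
        ``(m, 2)`` array of prediction coordinates.
    """
    points = _dedupe(points)
    n = len(points)
    if n < 3:
        raise ValueError("kriging needs at least 3 distinct points")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    coords = np.column_stack([points.x, points.y])

    gamma_dd = model(cdist(coords, coords))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma_dd
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0

    gamma_dt = model(cdist(coords, targets))  # (n, m)
    B = np.vstack([gamma_dt, np.ones(targets.shape[0])])
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A, B, rcond=None)
    weights, mu = sol[:n], sol[n]
    preds = weights.T @ points.values
    variance = np.einsum("ij,ij->j", weights, gamma_dt) + mu
    return preds, np.maximum(variance, 0.0)
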