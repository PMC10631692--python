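"""Global and local Moran's I on the fishnet lattice.

Global Moran's I measures whether grid-cell risk values cluster in space:

    I = sum_ij w_ij (x_i - xbar)(x_j - xbar) / (S^2 * sum_ij w_ij),
    S^2 = (1/n) sum_i (x_i - xbar)^2

Local Moran's I (Anselin LISA) attributes clustering to individual cells,
I_i = z_i / m2 * sum_j w_ij z_j with m2 = sum z^2 / n; significant cells
are labeled HH/LL (clusters) or HL/LH (outliers) by the quadrant of
(z_i, spatial lag of z_i).  Inference by both the normality approximation
(z-score) and seeded (conditional) permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import Fishnet

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "build_weights",
    "global_morans_i",
    "local_morans_i",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Sparse contiguity weights: neighbor lists plus aligned weight lists."""

    neighbors: list[np.ndarray]  # per unit, indices of neighbors
    weights: list[np.ndarray]  # per unit, aligned w_ij > 0
    standardized: bool

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def total_weight(self) -> float:
        return float(sum(w.sum() for w in self.weights))

    def islands(self) -> list[int]:
        return [i for i, nb in enumerate(self.neighbors) if nb.size == 0]

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatial lag sum_j w_ij z_j for every unit."""
        out = np.zeros(self.n)
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            if nb.size:
                out[i] = w @ z[nb]
        return out

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            W[i, nb] = w
        return W


def build_weights(
    net: Fishnet,
    scheme: str = "rook",
    standardize: bool = True,
) -> SpatialWeights:
    """Contiguity weights from fishnet lattice indices.

    Rook: cells sharing an edge (|dr| + |dc| = 1); queen additionally joins
    corner-touching cells.  Row standardization divides each row by its
    neighbor count.  Island cells (no neighbors) are reported with a warning.
    """
    if len(net) < 2:
        raise ValueError("need at least 2 cells")
    if scheme not in {"rook", "queen"}:
        raise ValueError("scheme must be 'rook' or 'queen'")
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(net.rows, net.cols))}
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    neighbors, weights = [], []
    for r, c in zip(net.rows, net.cols):
        nb = [index[(r + dr, c + dc)] for dr, dc in offsets
              if (r + dr, c + dc) in index]
        nb = np.array(sorted(nb), dtype=int)
        if nb.size and standardize:
            w = np.full(nb.size, 1.0 / nb.size)
        else:
            w = np.ones(nb.size)
        neighbors.append(nb)
        weights.append(w)
    sw = SpatialWeights(neighbors, weights, standardized=standardize)
    isl = sw.islands()
    if isl:
        logger.warning("island cells with no neighbors: %s", isl)
    return sw


@dataclass
class MoranResult:
    """Global or local Moran's I with inference."""

    I: float | None
    expected: float
    z_norm: float | None = None
    p_norm: float | None = None
    p_perm: float | None = None
    n_permutations: int = 0
    local_i: np.ndarray | None = None
    local_p: np.ndarray | None = None
    labels: np.ndarray | None = None  # HH/LL/LH/HL/ns
    method: str = "normal+permutation"


def _checked_values(values, W: SpatialWeights) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.size != W.n:
        raise ValueError("values must align with the weights")
    if np.var(x) == 0:
        raise ValueError("constant field has undefined Moran's I")
    return x


def _global_i(z: np.ndarray, W: SpatialWeights) -> float:
    n = z.size
    s2 = float(z @ z) / n
    num = float(z @ W.lag(z))
    return num / (s2 * W.total_weight)


def global_morans_i(
    values,
    W: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with normal-approximation z-score and permutation p.

    The permutation p-value is the pseudo p under ``n_permutations`` random
    relabelings of the values over the lattice (seeded, one-sided toward
    the observed sign of I - E[I]).
    """
    x = _checked_values(values, W)
    n = x.size
    z = x - x.mean()
    I_obs = _global_i(z, W)
    expected = -1.0 / (n - 1)

    # variance under the normality assumption (Cliff & Ord)
    Wd = W.dense()
    s0 = Wd.sum()
    s1 = 0.5 * ((Wd + Wd.T) ** 2).sum()
    s2 = ((Wd.sum(axis=0) + Wd.sum(axis=1)) ** 2).sum()
    var_norm = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - expected**2
    z_norm = (I_obs - expected) / np.sqrt(var_norm)
    from scipy.stats import norm as _norm

    p_norm = 2.0 * _norm.sf(abs(z_norm))

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(n_permutations)
        for k in range(n_permutations):
            sims[k] = _global_i(rng.permutation(z), W)
        if I_obs >= expected:
            extreme = int((sims >= I_obs).sum())
        else:
            extreme = int((sims <= I_obs).sum())
        p_perm = (extreme + 1) / (n_permutations + 1)

    return MoranResult(I=float(I_obs), expected=expected, z_norm=float(z_norm),
                       p_norm=float(p_norm), p_perm=p_perm,
                       n_permutations=n_permutations)


def local_morans_i(
    values,
    W: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> MoranResult:
    """Local Moran's I with conditional-permutation inference and labels.

    For each unit the observed statistic is compared against permutations
    that hold z_i fixed and redraw its neighbors from the remaining values.
    Units significant at ``alpha`` get a quadrant label (HH, LL, LH, HL);
    the rest are "ns".
    """
    x = _checked_values(values, W)
    n = x.size
    z = x - x.mean()
    m2 = float(z @ z) / n
    lag = W.lag(z)
    local = z / m2 * lag

    rng = np.random.default_rng(seed)
    p = np.ones(n)
    for i in range(n):
        nb = W.neighbors[i]
        if nb.size == 0:
            continue
        others = np.delete(z, i)
        w = W.weights[i]
        sims = np.empty(n_permutations)
        for k in range(n_permutations):
            draw = rng.choice(others, size=nb.size, replace=False)
            sims[k] = z[i] / m2 * (w @ draw)
        if local[i] >= 0:
            extreme = int((sims >= local[i]).sum())
        else:
            extreme = int((sims <= local[i]).sum())
        p[i] = (extreme + 1) / (n_permutations + 1)

    labels = np.full(n, "ns", dtype=object)
    sig = p <= alpha
    hi = z > 0
    lag_hi = lag > 0
    labels[sig & hi & lag_hi] = "HH"
    labels[sig & ~hi & ~lag_hi] = "LL"
    labels[sig & hi & ~lag_hi] = "HL"
    labels[sig & ~hi & lag_hi] = "LH"

    return MoranResult(I=None, expected=-1.0 / (n - 1), local_i=local,
                       local_p=p, labels=labels, n_permutations=n_permutations,
                       method="conditional-permutation")
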