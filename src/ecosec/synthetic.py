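"""Synthetic landscape and random-field generators with known ground truth.

Everything downstream of a classified land-use map is testable against these
generators: categorical rasters with controlled per-class area fractions and
patch clumping, epoch-to-epoch land conversion (e.g. forest giving way to
rubber plantations), and Gaussian random fields with a prescribed variogram
for the geostatistics stages.

All randomness flows from one integer seed through a named
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .raster import LandUseRaster

__all__ = [
    "ClassSpec",
    "TransitionRule",
    "FieldSpec",
    "PointSamples",
    "generate_landuse_raster",
    "evolve_landuse",
    "generate_autocorrelated_points",
]

# rook neighborhood, shared everywhere a patch or adjacency is defined
ROOK_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class ClassSpec:
    """Target composition of one land-use class in a synthetic raster.

    ``clumping`` controls patch aggregation: 0 gives salt-and-pepper noise
    (roughly one seed per cell), large values give few compact patches.
    """

    class_code: int
    target_fraction: float
    clumping: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")
        if self.clumping < 0:
            raise ValueError("clumping must be non-negative")


def _validate_specs(specs: list[ClassSpec]) -> None:
    codes = [s.class_code for s in specs]
    if len(set(codes)) != len(codes):
        raise ValueError("class codes must be unique")
    total = sum(s.target_fraction for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"target fractions must sum to 1 (got {total})")


@dataclass(frozen=True)
class TransitionRule:
    """Per-epoch conversion of one class into another.

    ``rate`` is the baseline per-cell conversion probability; it is
    multiplied by ``adjacency_bias`` (then clipped to 1) for cells that
    already touch the destination class, emulating frontier-style expansion.
    """

    from_code: int
    to_code: int
    rate: float
    adjacency_bias: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")
        if self.adjacency_bias < 1.0:
            raise ValueError("adjacency_bias must be >= 1")


@dataclass(frozen=True)
class FieldSpec:
    """Isotropic variogram of a stationary Gaussian random field."""

    model_family: str  # "spherical" or "exponential"
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.model_family not in {"spherical", "exponential"}:
            raise ValueError("model_family must be 'spherical' or 'exponential'")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be non-negative")
        if self.range_ <= 0:
            raise ValueError("range_ must be positive")


@dataclass
class PointSamples:
    """Scattered point observations: coordinates plus one value per point."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.x.shape == self.y.shape == self.values.shape):
            raise ValueError("x, y and values must have identical shapes")

    def __len__(self) -> int:
        return self.x.size

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.x, self.y, self.values]),
            delimiter=",",
            header="x,y,value",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "PointSamples":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])


def _class_quotas(n_cells: int, specs: list[ClassSpec]) -> np.ndarray:
    """Integer cell quota per class, largest-remainder rounding to n_cells."""
    exact = np.array([s.target_fraction * n_cells for s in specs])
    quotas = np.floor(exact).astype(int)
    remainder = n_cells - quotas.sum()
    order = np.argsort(-(exact - quotas))
    quotas[order[:remainder]] += 1
    return quotas


def generate_landuse_raster(
    n_rows: int,
    n_cols: int,
    specs: list[ClassSpec],
    seed: int,
    cell_size: float = 1000.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LandUseRaster:
    """Generate a categorical raster by seeded region growing.

    Each class receives an exact cell quota (largest-remainder rounding of
    its target fraction) and a number of seed cells controlled by its
    ``clumping``: ``n_seeds = ceil(quota / (1 + clumping))``.  Classes are
    placed from rarest to most abundant; each grows from its seeds over a
    uniform random priority field into free cells until its quota fills,
    and the most abundant class takes the remaining space as the landscape
    matrix.  Realized fractions therefore match targets exactly up to quota
    rounding, and patch counts fall as clumping rises.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions, each at least 8.
    specs
        Class composition; fractions must sum to 1.
    seed
        Seed for the single generator driving seeds, priorities and growth.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("raster must be at least 8x8")
    _validate_specs(specs)
    specs = [s for s in specs if s.target_fraction > 0]
    n_cells = n_rows * n_cols
    quotas = _class_quotas(n_cells, specs)
    if np.any(quotas == 0):
        bad = [s.class_code for s, q in zip(specs, quotas) if q == 0]
        raise ValueError(
            f"raster too small to realize classes {bad} at their fractions"
        )

    rng = np.random.default_rng(seed)
    out = np.full((n_rows, n_cols), -1, dtype=np.int64)
    rows_grid, cols_grid = np.mgrid[0:n_rows, 0:n_cols]

    order = np.argsort(quotas, kind="stable")  # rarest first, matrix last
    for pos in order[:-1]:
        spec_i, quota = specs[pos], int(quotas[pos])
        n_seeds = min(int(np.ceil(quota / (1.0 + spec_i.clumping))), quota)
        free = np.flatnonzero(out.ravel() == -1)
        seeds = rng.choice(free, size=n_seeds, replace=False)
        if n_seeds == quota:  # salt-and-pepper: the seeds ARE the class
            out.ravel()[seeds] = spec_i.class_code
            continue
        sr, sc = np.divmod(seeds, n_cols)
        # compact growth: priority = distance to the nearest seed plus noise
        # (noise roughens patch edges without fragmenting the complement)
        dist = np.min(
            np.hypot(rows_grid[..., None] - sr, cols_grid[..., None] - sc),
            axis=-1,
        )
        priority = dist + 1.5 * rng.random((n_rows, n_cols))
        heap: list[tuple[float, int, int]] = []
        for cell in seeds:
            r, c = divmod(int(cell), n_cols)
            heapq.heappush(heap, (priority[r, c], r, c))
        placed = 0
        while placed < quota:
            if not heap:
                # frontier fully enclosed by other classes: re-seed
                free = np.flatnonzero(out.ravel() == -1)
                cell = int(free[rng.integers(free.size)])
                r, c = divmod(cell, n_cols)
                heapq.heappush(heap, (priority[r, c], r, c))
                continue
            _, r, c = heapq.heappop(heap)
            if out[r, c] != -1:
                continue
            out[r, c] = spec_i.class_code
            placed += 1
            for dr, dc in ROOK_OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and out[rr, cc] == -1:
                    heapq.heappush(heap, (priority[rr, cc], rr, cc))
    out[out == -1] = specs[order[-1]].class_code

    return LandUseRaster(out, cell_size=cell_size, origin=origin)


def evolve_landuse(
    raster: LandUseRaster,
    rules: list[TransitionRule],
    seed: int,
) -> LandUseRaster:
    """Apply one epoch of stochastic land conversion (synchronous update).

    Adjacency (any rook neighbor already holding ``to_code`` in the *input*
    raster) multiplies the rule's rate by ``adjacency_bias``, clipped to 1.
    Cell count and grid geometry are preserved; only cells matching a rule's
    ``from_code`` may change.
    """
    legend_codes = set(int(c) for c in raster.class_codes())
    for rule in rules:
        if rule.from_code not in legend_codes or rule.to_code not in legend_codes:
            raise ValueError(
                f"rule {rule.from_code}->{rule.to_code} references codes absent "
                f"from the raster legend {sorted(legend_codes)}"
            )
    rng = np.random.default_rng(seed)
    src = raster.data
    out = src.copy()
    for rule in rules:
        eligible = src == rule.from_code
        if not eligible.any():
            continue
        touches = np.zeros_like(eligible)
        is_dst = src == rule.to_code
        touches[:-1, :] |= is_dst[1:, :]
        touches[1:, :] |= is_dst[:-1, :]
        touches[:, :-1] |= is_dst[:, 1:]
        touches[:, 1:] |= is_dst[:, :-1]
        prob = np.where(
            touches, np.minimum(rule.rate * rule.adjacency_bias, 1.0), rule.rate
        )
        convert = eligible & (rng.random(src.shape) < prob)
        out[convert] = rule.to_code
    return LandUseRaster(out, raster.cell_size, raster.origin, raster.nodata,
                         dict(raster.legend))


def variogram_value(family: str, h: np.ndarray, nugget: float,
                    partial_sill: float, range_: float) -> np.ndarray:
    """Theoretical semivariance gamma(h) for spherical/exponential models.

    The exponential range is the *practical* range: gamma reaches 95% of the
    sill at h = range_.
    """
    h = np.asarray(h, dtype=float)
    if family == "spherical":
        ratio = np.clip(h / range_, 0.0, 1.0)
        struct = 1.5 * ratio - 0.5 * ratio**3
    elif family == "exponential":
        struct = 1.0 - np.exp(-3.0 * h / range_)
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    gamma = nugget + partial_sill * struct
    return np.where(h == 0, 0.0, gamma)


def generate_autocorrelated_points(
    n_points: int,
    extent: tuple[float, float, float, float],
    spec: FieldSpec,
    seed: int,
) -> PointSamples:
    """Sample a zero-mean Gaussian random field at uniform random locations.

    Exact simulation by Cholesky factorization of the point covariance
    matrix C(h) = partial_sill * (1 - gamma_struct(h)) with the nugget on
    the diagonal; intended for n up to a couple of thousand points.

    Parameters
    ----------
    n_points
        At least 30 (variogram estimation below that is meaningless).
    extent
        ``(xmin, ymin, xmax, ymax)`` of the sampling rectangle.
    """
    if n_points < 30:
        raise ValueError("need at least 30 points for a usable random field")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    rng = np.random.default_rng(seed)
    x = rng.uniform(xmin, xmax, n_points)
    y = rng.uniform(ymin, ymax, n_points)
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    h = np.hypot(dx, dy)
    sill = spec.nugget + spec.partial_sill
    gamma = variogram_value(spec.model_family, h, spec.nugget,
                            spec.partial_sill, spec.range_)
    cov = sill - gamma  # C(0)=sill on the diagonal (includes the nugget)
    # tiny jitter guards the factorization against numerically semidefinite C
    cov[np.diag_indices_from(cov)] += 1e-10 * max(sill, 1.0)
    chol = np.linalg.cholesky(cov)
    values = chol @ rng.standard_normal(n_points)
    return PointSamples(x, y, values)
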