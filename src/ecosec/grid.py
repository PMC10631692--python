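"""Fishnet evaluation grid, grid-cell ecological risk and security grades.

The study area is tessellated into square "risk community" cells (fishnet).
Each cell's ecological risk index is the area-weighted mean of the per-class
loss indices of the land it contains:

    ERI_k = sum_i (A_ki / A_k) * R_i

so ERI is always a convex combination of the class R values.  ERI is then
classified into five security grades: grade I (lowest risk, highest
security) through grade V.  The default breakpoints are a fixed scheme so
epochs remain comparable; Jenks natural breaks are available as an
alternative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box, mapping, shape

from .raster import LandUseRaster

__all__ = [
    "Fishnet",
    "RiskGrid",
    "GradeScheme",
    "DEFAULT_GRADE_SCHEME",
    "GRADE_LABELS",
    "build_fishnet",
    "compute_eri",
    "classify_grades",
    "jenks_breaks",
    "grade_area_proportions",
    "grade_transition_matrix",
    "load_boundary",
    "save_boundary",
]

logger = logging.getLogger(__name__)

GRADE_LABELS = ("I", "II", "III", "IV", "V")


@dataclass
class Fishnet:
    """Axis-aligned square-cell tessellation clipped to a study boundary.

    ``rows``/``cols`` index cells on the bounding-box lattice anchored at
    the boundary's lower-left corner; ``area`` is each cell's in-boundary
    (clipped) area in m^2.
    """

    cell_size: float  # meters
    origin: tuple[float, float]  # lower-left corner of the bounding box
    rows: np.ndarray
    cols: np.ndarray
    area: np.ndarray  # clipped in-boundary area, m^2
    centers: np.ndarray  # (n, 2) cell-center coordinates

    def __len__(self) -> int:
        return self.rows.size

    @property
    def cell_km(self) -> float:
        return self.cell_size / 1000.0

    def cell_polygon(self, i: int) -> Polygon:
        x0 = self.origin[0] + self.cols[i] * self.cell_size
        y0 = self.origin[1] + self.rows[i] * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def to_geojson(self, path: str | Path, properties: pd.DataFrame | None = None) -> None:
        feats = []
        for i in range(len(self)):
            props = {"row": int(self.rows[i]), "col": int(self.cols[i]),
                     "area_m2": float(self.area[i])}
            if properties is not None:
                props.update({k: _jsonable(v) for k, v in properties.iloc[i].items()})
            feats.append({"type": "Feature",
                          "geometry": mapping(self.cell_polygon(i)),
                          "properties": props})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


@dataclass
class RiskGrid:
    """Per-fishnet-cell ERI values and security grades for one epoch."""

    net: Fishnet
    eri: np.ndarray
    grades: np.ndarray  # integer 1..5
    epoch: str = ""
    class_fractions: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.net)

    def grade_labels(self) -> np.ndarray:
        return np.array([GRADE_LABELS[g - 1] for g in self.grades])


@dataclass(frozen=True)
class GradeScheme:
    """Five ordered risk intervals mapping ERI to security grades I..V.

    Intervals are left-closed/right-open, the last closed.  Grade I is the
    lowest-risk (highest-security) interval.
    """

    breakpoints: tuple[float, ...] = (0.042, 0.049, 0.056, 0.06)
    upper: float = 1.0
    provenance: str = "fixed-table"

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if len(bp) != 4 or any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("need 4 strictly increasing breakpoints")
        if self.upper <= bp[-1]:
            raise ValueError("upper bound must exceed the last breakpoint")


DEFAULT_GRADE_SCHEME = GradeScheme()


def load_boundary(path: str | Path) -> Polygon:
    """Read a study-area polygon from a GeoJSON file (first feature)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    poly = shape(geom)
    if poly.is_empty or not poly.is_valid:
        raise ValueError(f"invalid boundary geometry in {path}")
    return poly


def save_boundary(poly: Polygon, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "Feature", "geometry": mapping(poly),
                   "properties": {}}, fh)


def build_fishnet(
    boundary: Polygon,
    cell_km: float = 10.0,
    min_cover_frac: float = 0.01,
) -> Fishnet:
    """Tile the boundary's bounding box with square cells and clip.

    Cells are anchored at the bounding-box lower-left corner.  Only cells
    intersecting the boundary are retained; cells whose in-boundary area is
    below ``min_cover_frac`` of a full cell are dropped (boundary slivers).
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if boundary.is_empty or not boundary.is_valid:
        raise ValueError("invalid boundary geometry")
    cell = cell_km * 1000.0
    xmin, ymin, xmax, ymax = boundary.bounds
    n_cols = int(np.ceil((xmax - xmin) / cell - 1e-12))
    n_rows = int(np.ceil((ymax - ymin) / cell - 1e-12))
    rows, cols, areas, centers = [], [], [], []
    shapely.prepare(boundary)
    for r in range(n_rows):
        for c in range(n_cols):
            x0, y0 = xmin + c * cell, ymin + r * cell
            cell_poly = box(x0, y0, x0 + cell, y0 + cell)
            if not boundary.intersects(cell_poly):
                continue
            clipped = boundary.intersection(cell_poly)
            a = clipped.area
            if a < min_cover_frac * cell * cell:
                if a > 0:
                    logger.debug("dropping sliver cell (%d, %d), area %.1f m2", r, c, a)
                continue
            rows.append(r)
            cols.append(c)
            areas.append(a)
            centers.append((x0 + cell / 2, y0 + cell / 2))
    if not rows:
        raise ValueError("no fishnet cell intersects the boundary")
    return Fishnet(
        cell_size=cell,
        origin=(xmin, ymin),
        rows=np.asarray(rows),
        cols=np.asarray(cols),
        area=np.asarray(areas),
        centers=np.asarray(centers),
    )


def compute_eri(
    net: Fishnet,
    raster: LandUseRaster,
    loss: dict[int, float],
    boundary: Polygon | None = None,
    scheme: GradeScheme = DEFAULT_GRADE_SCHEME,
    epoch: str = "",
) -> RiskGrid:
    """Area-weighted ecological risk index per fishnet cell.

    Raster cells are assigned to fishnet cells by their center coordinates;
    when a boundary is given, raster cells outside it are ignored so ERI
    reflects in-boundary land only.  Fishnet cells containing no usable
    raster cell are dropped with a warning.
    """
    missing = [c for c in raster.class_counts() if c not in loss]
    if missing:
        raise ValueError(f"no loss index R for raster classes {missing}")

    xs, ys = raster.cell_centers()
    data = raster.data
    usable = data != raster.nodata
    if boundary is not None:
        usable &= shapely.contains_xy(boundary, xs, ys)

    col_idx = np.floor((xs - net.origin[0]) / net.cell_size).astype(int)
    row_idx = np.floor((ys - net.origin[1]) / net.cell_size).astype(int)
    key = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(net.rows, net.cols))}

    n = len(net)
    cell_total = np.zeros(n)
    codes = sorted(raster.class_counts())
    code_pos = {c: i for i, c in enumerate(codes)}
    class_cells = np.zeros((n, len(codes)))
    rr, cc = row_idx[usable], col_idx[usable]
    vv = data[usable]
    for r, c, v in zip(rr.ravel(), cc.ravel(), vv.ravel()):
        i = key.get((r, c))
        if i is None:
            continue
        cell_total[i] += 1
        class_cells[i, code_pos[int(v)]] += 1

    keep = cell_total > 0
    if not keep.all():
        logger.warning("%d fishnet cells contain no usable raster cells; dropped",
                       int((~keep).sum()))
    fractions = class_cells[keep] / cell_total[keep, None]
    r_vec = np.array([loss[c] for c in codes])
    eri = fractions @ r_vec

    sub = Fishnet(net.cell_size, net.origin, net.rows[keep], net.cols[keep],
                  net.area[keep], net.centers[keep])
    grades = classify_grades(eri, scheme)
    frac_df = pd.DataFrame(fractions, columns=[f"frac_{c}" for c in codes])
    return RiskGrid(sub, eri, grades, epoch=epoch, class_fractions=frac_df)


def classify_grades(values, scheme: GradeScheme = DEFAULT_GRADE_SCHEME) -> np.ndarray:
    """Map risk values to grades 1..5 (I..V).

    Left-closed/right-open intervals; a value exactly on a breakpoint falls
    into the higher grade; the top interval is closed at ``scheme.upper``.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("risk values must be finite")
    if (v < 0).any() or (v > scheme.upper).any():
        raise ValueError(f"risk values must lie in [0, {scheme.upper}]")
    grades = np.searchsorted(np.asarray(scheme.breakpoints), v, side="right") + 1
    return grades.astype(int)


def jenks_breaks(values, n_classes: int = 5) -> GradeScheme:
    """Jenks natural breaks by exact dynamic programming (Fisher's method).

    Minimizes total within-class sum of squared deviations.  Returns a
    :class:`GradeScheme` whose breakpoints are midpoints between adjacent
    class boundary values, so classification is reproducible on new data.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < n_classes:
        raise ValueError("need at least as many values as classes")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csq = np.concatenate([[0.0], np.cumsum(v**2)])

    def ssd(i, j):  # within-class SSD of v[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / m

    cost = np.full((n_classes + 1, n + 1), np.inf)
    back = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_classes + 1):
        for j in range(k, n + 1):
            for i in range(k - 1, j):
                c = cost[k - 1, i] + ssd(i, j)
                if c < cost[k, j]:
                    cost[k, j] = c
                    back[k, j] = i
    bounds = []
    j = n
    for k in range(n_classes, 0, -1):
        i = back[k, j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]  # drop leading 0; class start indices
    breakpoints = tuple((v[i - 1] + v[i]) / 2.0 for i in bounds)
    upper = max(float(v[-1]), breakpoints[-1] + 1e-12)
    return GradeScheme(breakpoints=breakpoints, upper=upper, provenance="jenks")


def grade_area_proportions(grades, areas) -> pd.Series:
    """Percent of study area per grade, weighted by cell (clipped) area."""
    grades = np.asarray(grades)
    areas = np.asarray(areas, dtype=float)
    if grades.shape != areas.shape:
        raise ValueError("grades and areas must align")
    total = areas.sum()
    out = pd.Series(0.0, index=list(GRADE_LABELS))
    for g in range(1, 6):
        out.iloc[g - 1] = 100.0 * areas[grades == g].sum() / total
    return out


def grade_transition_matrix(grid_a: RiskGrid, grid_b: RiskGrid) -> pd.DataFrame:
    """5x5 grade-transition areas (km^2) between two epochs on one fishnet.

    Row sums reproduce epoch-a grade areas, column sums epoch-b grade areas.
    """
    na, nb = grid_a.net, grid_b.net
    same = (
        len(na) == len(nb)
        and na.cell_size == nb.cell_size
        and np.array_equal(na.rows, nb.rows)
        and np.array_equal(na.cols, nb.cols)
    )
    if not same:
        raise ValueError("the two grids must share the same fishnet")
    mat = np.zeros((5, 5))
    km2 = na.area / 1e6
    for ga, gb, a in zip(grid_a.grades, grid_b.grades, km2):
        mat[ga - 1, gb - 1] += a
    return pd.DataFrame(mat, index=list(GRADE_LABELS), columns=list(GRADE_LABELS))
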