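"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ecosec import ClassSpec, generate_landuse_raster
from ecosec.raster import LandUseRaster

# Published per-class landscape metrics of a prefecture-scale six-class
# assessment, used as input data for index arithmetic:
# (class, year, C, S, D, E, F, R).  Two cells are internally inconsistent
# with the index definitions (tea 1996 E; forestry 2017 R) and are flagged.
PUBLISHED_CLASS_METRICS = [
    ("forestry", 1996, 0.004, 0.037, 1.252, 0.263, 0.10, 0.026),
    ("forestry", 2003, 0.004, 0.039, 1.250, 0.264, 0.10, 0.026),
    ("forestry", 2010, 0.009, 0.063, 0.939, 0.211, 0.10, 0.021),
    ("forestry", 2017, 0.008, 0.060, 1.268, 0.275, 0.10, 0.021),
    ("rubber", 1996, 0.047, 0.258, 1.388, 0.379, 0.28, 0.106),
    ("rubber", 2003, 0.049, 0.268, 1.375, 0.380, 0.28, 0.106),
    ("rubber", 2010, 0.015, 0.108, 0.990, 0.238, 0.28, 0.067),
    ("rubber", 2017, 0.020, 0.135, 1.323, 0.315, 0.28, 0.088),
    ("tea", 1996, 0.205, 0.784, 1.329, 0.903, 0.24, 0.217),
    ("tea", 2003, 0.123, 0.661, 1.403, 0.540, 0.24, 0.130),
    ("tea", 2010, 0.112, 0.631, 1.330, 0.511, 0.24, 0.123),
    ("tea", 2017, 0.064, 0.436, 1.358, 0.434, 0.24, 0.104),
    ("cultivated", 1996, 0.115, 0.768, 1.376, 0.563, 0.14, 0.079),
    ("cultivated", 2003, 0.072, 0.724, 1.285, 0.510, 0.14, 0.072),
    ("cultivated", 2010, 0.049, 0.504, 1.286, 0.433, 0.14, 0.061),
    ("cultivated", 2017, 0.064, 0.456, 1.352, 0.439, 0.14, 0.062),
    ("built_up", 1996, 0.082, 1.387, 1.253, 0.708, 0.05, 0.035),
    ("built_up", 2003, 0.169, 2.030, 1.299, 0.953, 0.05, 0.048),
    ("built_up", 2010, 0.085, 2.271, 1.159, 0.956, 0.05, 0.048),
    ("built_up", 2017, 0.146, 1.723, 1.311, 0.852, 0.05, 0.043),
    ("water", 1996, 0.156, 2.712, 1.251, 1.142, 0.19, 0.217),
    ("water", 2003, 0.622, 2.715, 1.339, 1.393, 0.19, 0.265),
    ("water", 2010, 0.093, 2.769, 1.188, 1.115, 0.19, 0.212),
    ("water", 2017, 0.111, 2.502, 1.222, 1.051, 0.19, 0.200),
]
INCONSISTENT_E_CELLS = {("tea", 1996)}
INCONSISTENT_R_CELLS = {("forestry", 2017)}


def flood_fill_patches(data: np.ndarray, nodata: int = -9999):
    """Brute-force rook-connected patch inventory, independent of the package.

    Returns a list of (class_code, cell_count, perimeter) tuples; perimeter
    counts cell edges facing a different class, nodata, or the array edge.
    """
    n_rows, n_cols = data.shape
    seen = np.zeros(data.shape, dtype=bool)
    patches = []
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if seen[r0, c0] or data[r0, c0] == nodata:
                continue
            code = data[r0, c0]
            stack = [(r0, c0)]
            seen[r0, c0] = True
            cells = 0
            perim = 0
            while stack:
                r, c = stack.pop()
                cells += 1
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                        perim += 1
                    elif data[rr, cc] != code:
                        perim += 1
                    elif not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            patches.append((int(code), cells, perim))
    return patches


@pytest.fixture
def two_class_raster() -> LandUseRaster:
    """64x64 salt-and-pepper raster with two equal classes, fixed seed."""
    specs = [ClassSpec(1, 0.5, clumping=0.0), ClassSpec(2, 0.5, clumping=0.0)]
    return generate_landuse_raster(64, 64, specs, seed=7)


@pytest.fixture
def clumped_raster() -> LandUseRaster:
    """32x32 raster with three clumped classes for patch-oracle checks."""
    specs = [
        ClassSpec(1, 0.6, clumping=30.0),
        ClassSpec(2, 0.3, clumping=10.0),
        ClassSpec(3, 0.1, clumping=4.0),
    ]
    return generate_landuse_raster(32, 32, specs, seed=3)
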