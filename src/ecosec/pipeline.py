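"""End-to-end orchestration: rasters in, security-assessment report out.

Stages run in dependency order: per-class structure metrics and loss
indices -> fishnet risk grid -> variogram fit and ordinary kriging ->
security grades and transitions -> spatial autocorrelation -> gravity-center
migration -> GM(1,1) forecasts.  A single YAML config describes the run;
identical config + seed reproduce the report exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from . import __version__
from .geostat import (empirical_variogram, fit_variogram_model,
                      nugget_sill_ratio, ordinary_kriging)
from .gravity import security_centroid, transfer_angle, transfer_distance
from .grey import forecast_risk_grid
from .grid import (DEFAULT_GRADE_SCHEME, GradeScheme, RiskGrid, build_fishnet,
                   compute_eri, grade_area_proportions,
                   grade_transition_matrix, load_boundary, save_boundary)
from .metrics import DisturbanceWeights, VulnerabilityTable, metrics_table
from .moran import build_weights, global_morans_i, local_morans_i
from .raster import LandUseRaster
from .synthetic import ClassSpec, PointSamples, TransitionRule, generate_landuse_raster, evolve_landuse

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_demo_dataset",
           "DEMO_CLASSES"]

logger = logging.getLogger(__name__)

# demo legend: code -> (name, vulnerability F)
DEMO_CLASSES = {
    1: ("forest", 0.10),
    2: ("rubber", 0.28),
    3: ("tea", 0.24),
    4: ("cultivated", 0.14),
    5: ("built_up", 0.05),
    6: ("water", 0.19),
}


@dataclass
class RunConfig:
    """Validated run description (normally read from YAML)."""

    epochs: list[dict]  # each: {label, raster}
    boundary: str
    vulnerability: dict[int, float]
    cell_km: float = 10.0
    disturbance_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    grade_breakpoints: tuple[float, ...] = DEFAULT_GRADE_SCHEME.breakpoints
    variogram_family: str = "spherical"
    weights_scheme: str = "rook"
    n_permutations: int = 999
    seed: int = 0
    forecast_horizons: list[int] = field(default_factory=lambda: [1, 2])
    base_dir: Path = Path(".")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(
            epochs=raw["epochs"],
            boundary=raw["boundary"],
            vulnerability={int(k): float(v) for k, v in raw["vulnerability"].items()},
            cell_km=float(raw.get("cell_km", 10.0)),
            disturbance_weights=tuple(raw.get("disturbance_weights", (0.5, 0.3, 0.2))),
            grade_breakpoints=tuple(
                raw.get("grade_breakpoints", DEFAULT_GRADE_SCHEME.breakpoints)
            ),
            variogram_family=raw.get("variogram_family", "spherical"),
            weights_scheme=raw.get("weights_scheme", "rook"),
            n_permutations=int(raw.get("n_permutations", 999)),
            seed=int(raw.get("seed", 0)),
            forecast_horizons=list(raw.get("forecast_horizons", [1, 2])),
            base_dir=path.parent,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.epochs:
            raise ValueError("config lists no epochs")
        for ep in self.epochs:
            p = self.base_dir / ep["raster"]
            if not p.exists():
                raise ValueError(f"raster not found: {p}")
        if not (self.base_dir / self.boundary).exists():
            raise ValueError(f"boundary not found: {self.base_dir / self.boundary}")
        DisturbanceWeights(*self.disturbance_weights)
        VulnerabilityTable(self.vulnerability)
        GradeScheme(self.grade_breakpoints)
        if self.forecast_horizons and len(self.epochs) < 4:
            raise ValueError(
                "grey forecasting needs at least 4 epochs; "
                f"config has {len(self.epochs)} (drop forecast_horizons or add epochs)"
            )

    def content_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "base_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """All tables of a pipeline run plus provenance."""

    class_metrics: pd.DataFrame
    variograms: pd.DataFrame
    grade_proportions: pd.DataFrame  # epochs x grades, percent
    moran_global: pd.DataFrame
    transitions: dict[str, pd.DataFrame]
    gravity_track: pd.DataFrame
    forecast_diagnostics: pd.DataFrame | None
    risk_grids: dict[str, RiskGrid]
    warnings: list[str]
    provenance: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.class_metrics.to_csv(out / "class_metrics.csv", index=False)
        self.variograms.to_csv(out / "variograms.csv", index=False)
        self.grade_proportions.to_csv(out / "grade_proportions.csv")
        self.moran_global.to_csv(out / "moran_global.csv", index=False)
        for label, mat in self.transitions.items():
            mat.to_csv(out / f"transition_{label}.csv")
        self.gravity_track.to_csv(out / "gravity_track.csv", index=False)
        if self.forecast_diagnostics is not None:
            self.forecast_diagnostics.to_csv(out / "forecast_diagnostics.csv",
                                             index=False)
        for label, rg in self.risk_grids.items():
            props = pd.DataFrame({"eri": rg.eri, "grade": rg.grade_labels()})
            rg.net.to_geojson(out / f"risk_grid_{label}.geojson", props)
        with open(out / "provenance.json", "w") as fh:
            json.dump({"provenance": self.provenance, "warnings": self.warnings},
                      fh, indent=2, default=str)


def _gravity_rows(grids: dict[str, RiskGrid]) -> pd.DataFrame:
    """Gravity track of every grade across consecutive epochs (km units)."""
    labels = list(grids)
    rows = []
    cents: dict[tuple[str, int], object] = {}
    for label, rg in grids.items():
        xs = rg.net.centers[:, 0] / 1000.0
        ys = rg.net.centers[:, 1] / 1000.0
        for g in range(1, 6):
            sel = rg.grades == g
            cents[(label, g)] = security_centroid(
                xs[sel], ys[sel], rg.net.area[sel] / 1e6,
                grade=("I", "II", "III", "IV", "V")[g - 1], epoch=label,
            ) if sel.any() else None
    for ep_m, ep_n in zip(labels, labels[1:]):
        for g in range(1, 6):
            pm, pn = cents[(ep_m, g)], cents[(ep_n, g)]
            grade = ("I", "II", "III", "IV", "V")[g - 1]
            period = f"{ep_m}~{ep_n}"
            if pm is None or pn is None:
                rows.append({"grade": grade, "period": period, "dx_km": np.nan,
                             "dy_km": np.nan, "distance_km": np.nan,
                             "bearing_deg": np.nan, "direction": "absent"})
                continue
            shift = transfer_angle(pm, pn, grade=grade, period=period)
            rows.append({"grade": grade, "period": period,
                         "dx_km": shift.dx_km, "dy_km": shift.dy_km,
                         "distance_km": shift.distance_km,
                         "bearing_deg": shift.bearing_deg,
                         "direction": shift.direction or "none"})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage on the configured epoch sequence."""
    config.validate()
    t_start = time.time()
    warnings_log: list[str] = []
    stage_times: dict[str, float] = {}

    def _stage(name):
        logger.info("stage: %s", name)
        stage_times[name] = time.time()

    _stage("load")
    boundary = load_boundary(config.base_dir / config.boundary)
    rasters = {ep["label"]: LandUseRaster.load(config.base_dir / ep["raster"])
               for ep in config.epochs}

    _stage("class_metrics")
    weights = DisturbanceWeights(*config.disturbance_weights)
    vuln = VulnerabilityTable(config.vulnerability)
    cmetrics = metrics_table(rasters, weights, vuln)

    _stage("risk_grid")
    scheme = GradeScheme(config.grade_breakpoints)
    net = build_fishnet(boundary, cell_km=config.cell_km)
    grids: dict[str, RiskGrid] = {}
    for label, raster in rasters.items():
        sub = cmetrics[cmetrics["epoch"] == label]
        loss = dict(zip(sub["class_code"], sub["R"]))
        grids[label] = compute_eri(net, raster, loss, boundary=boundary,
                                   scheme=scheme, epoch=label)

    _stage("geostatistics")
    vg_rows = []
    for label, rg in grids.items():
        pts = PointSamples(rg.net.centers[:, 0], rg.net.centers[:, 1], rg.eri)
        emp = empirical_variogram(pts)
        model = fit_variogram_model(emp, family=config.variogram_family)
        vg_rows.append({"epoch": label, "family": model.family,
                        "nugget": model.nugget, "sill": model.sill,
                        "nugget_sill_pct": nugget_sill_ratio(model),
                        "range_m": model.range_})
    variograms = pd.DataFrame(vg_rows)

    _stage("grades")
    props = pd.DataFrame(
        {label: grade_area_proportions(rg.grades, rg.net.area)
         for label, rg in grids.items()}
    ).T
    transitions = {}
    labels = list(grids)
    for a, b in zip(labels, labels[1:]):
        transitions[f"{a}_{b}"] = grade_transition_matrix(grids[a], grids[b])

    _stage("autocorrelation")
    first_net = grids[labels[0]].net
    W = build_weights(first_net, scheme=config.weights_scheme, standardize=True)
    if W.islands():
        warnings_log.append(f"island fishnet cells: {W.islands()}")
    moran_rows = []
    for k, (label, rg) in enumerate(grids.items()):
        res = global_morans_i(rg.eri, W, n_permutations=config.n_permutations,
                              seed=config.seed + k)
        local = local_morans_i(rg.eri, W, n_permutations=config.n_permutations,
                               seed=config.seed + 1000 + k)
        counts = pd.Series(local.labels).value_counts().to_dict()
        moran_rows.append({"epoch": label, "I": res.I, "z": res.z_norm,
                           "p_norm": res.p_norm, "p_perm": res.p_perm,
                           **{f"n_{lab}": counts.get(lab, 0)
                              for lab in ("HH", "LL", "LH", "HL", "ns")}})
    moran_global = pd.DataFrame(moran_rows)

    _stage("gravity")
    all_grids = dict(grids)

    forecast_diag = None
    if config.forecast_horizons:
        _stage("forecast")
        fgrids, forecast_diag = forecast_risk_grid(
            list(grids.values()), config.forecast_horizons, scheme=scheme
        )
        for fg in fgrids:
            label = f"forecast{fg.epoch}"
            all_grids[label] = fg
            props.loc[label] = grade_area_proportions(fg.grades, fg.net.area)

    gravity_track = _gravity_rows(all_grids)

    elapsed = time.time() - t_start
    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "ecosec_version": __version__,
        "numpy_version": np.__version__,
        "n_fishnet_cells": len(net),
        "elapsed_s": round(elapsed, 2),
        "defaults_echo": {
            "cell_km": config.cell_km,
            "disturbance_weights": list(config.disturbance_weights),
            "grade_breakpoints": list(config.grade_breakpoints),
            "variogram_family": config.variogram_family,
            "weights_scheme": config.weights_scheme,
            "n_permutations": config.n_permutations,
            "forecast_horizons": list(config.forecast_horizons),
        },
    }
    return RunReport(
        class_metrics=cmetrics,
        variograms=variograms,
        grade_proportions=props,
        moran_global=moran_global,
        transitions=transitions,
        gravity_track=gravity_track,
        forecast_diagnostics=forecast_diag,
        risk_grids=all_grids,
        warnings=warnings_log,
        provenance=provenance,
    )


def make_demo_dataset(out_dir: str | Path, seed: int = 42,
                      n_rows: int = 100, n_cols: int = 120,
                      cell_size: float = 1000.0) -> Path:
    """Write a ready-to-run 4-epoch synthetic demo (rasters, boundary, config).

    The epoch sequence emulates plantation expansion into natural forest:
    forest cover declines strictly across epochs while rubber and tea grow,
    and some cultivated land urbanizes.  Returns the config path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = [
        ClassSpec(1, 0.760, clumping=400.0),  # forest: one dominant matrix
        ClassSpec(2, 0.154, clumping=60.0),   # rubber plantations
        ClassSpec(3, 0.026, clumping=20.0),   # tea gardens
        ClassSpec(4, 0.046, clumping=15.0),   # cultivated
        ClassSpec(5, 0.010, clumping=5.0),    # built-up
        ClassSpec(6, 0.004, clumping=8.0),    # water
    ]
    rules = [
        TransitionRule(1, 2, rate=0.02, adjacency_bias=8.0),
        TransitionRule(1, 3, rate=0.005, adjacency_bias=6.0),
        TransitionRule(4, 5, rate=0.01, adjacency_bias=4.0),
    ]
    base = generate_landuse_raster(n_rows, n_cols, specs, seed=seed,
                                   cell_size=cell_size)
    epoch_labels = ["epoch1", "epoch2", "epoch3", "epoch4"]
    rasters = [base]
    for k in range(1, 4):
        rasters.append(evolve_landuse(rasters[-1], rules, seed=seed + k))
    for label, raster in zip(epoch_labels, rasters):
        raster.save(out / f"landuse_{label}.asc")

    w_km = n_cols * cell_size / 1000.0
    h_km = n_rows * cell_size / 1000.0
    boundary = Polygon([
        (0.02 * w_km * 1000, 0.0),
        (w_km * 1000, 0.10 * h_km * 1000),
        (0.97 * w_km * 1000, 0.95 * h_km * 1000),
        (0.45 * w_km * 1000, h_km * 1000),
        (0.0, 0.55 * h_km * 1000),
    ])
    save_boundary(boundary, out / "boundary.geojson")

    config = {
        "epochs": [{"label": lab, "raster": f"landuse_{lab}.asc"}
                   for lab in epoch_labels],
        "boundary": "boundary.geojson",
        "vulnerability": {code: f for code, (_, f) in DEMO_CLASSES.items()},
        "cell_km": 10.0,
        "disturbance_weights": [0.5, 0.3, 0.2],
        "variogram_family": "spherical",
        "weights_scheme": "rook",
        "n_permutations": 199,
        "seed": seed,
        "forecast_horizons": [1, 2],
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return cfg_path
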