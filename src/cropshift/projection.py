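"""Feature assembly, the iterated-subsample training protocol, and
scenario projection.

Training mirrors the study protocol: each iteration draws a random subset
of cells, splits it 70/30, grows one tree on a bootstrap of the 70 % and
scores it on the held-out 30 %; all iteration trees are pooled into one
bagged ensemble.  Because the protocol conflates two error estimates, both
are reported: the mean per-iteration holdout R²/MSE, and the pooled
ensemble's OOB R²/MSE over the full feature table.

Projection substitutes the scenario climatology's annual means and the
projected zones (PAEZ) into the feature table while GDP, fertiliser, soils
and elevation stay at baseline (static layers), then clamps the bagged
prediction into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aez import AEZMap
from .rf_core import (
    FeatureTable,
    Forest,
    default_mtry,
    fit_tree,
    oob_error,
    predict,
)
from .synthetic_data import CoverField, DriverStack, ScenarioSpec

__all__ = [
    "TrainingProtocol",
    "FittedModel",
    "ScenarioProjection",
    "FEATURE_COLUMNS",
    "assemble_features",
    "train_baseline",
    "project_scenario",
]

#: Fixed feature schema: name -> (DriverStack/AEZ source, categorical?).
FEATURE_COLUMNS = [
    ("mean_annual_temp", False),
    ("mean_annual_precip", False),
    ("aez", True),
    ("gdp_regional", False),
    ("n_fert", False),
    ("p_fert", False),
    ("soil_class", True),
    ("elevation", False),
]


@dataclass(frozen=True)
class TrainingProtocol:
    """Iterated-subsample protocol: n_iterations random subsets of
    cells_per_iteration cells, each split train_fraction/(1-train_fraction),
    one tree per iteration."""

    n_iterations: int = 200
    cells_per_iteration: int = 2000
    train_fraction: float = 0.70
    seed: int = 0
    mtry: int | None = None
    min_leaf: int = 5

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cells_per_iteration < 2:
            raise ValueError("cells_per_iteration must be >= 2")


@dataclass
class FittedModel:
    """Pooled ensemble plus both error bookkeepings and the frozen schema."""

    forest: Forest
    holdout_r2: np.ndarray   # per iteration
    holdout_mse: np.ndarray  # per iteration
    oob_mse: float
    oob_r2: float
    schema: dict
    protocol: TrainingProtocol

    @property
    def mean_holdout_r2(self) -> float:
        return float(np.nanmean(self.holdout_r2))

    @property
    def mean_holdout_mse(self) -> float:
        return float(np.nanmean(self.holdout_mse))

    def metrics(self) -> dict:
        return {
            "mean_holdout_r2": self.mean_holdout_r2,
            "mean_holdout_mse": self.mean_holdout_mse,
            "oob_r2": self.oob_r2,
            "oob_mse": self.oob_mse,
            "n_trees": self.forest.n_trees,
        }


@dataclass(frozen=True)
class ScenarioProjection:
    scenario: str
    cover_pred: CoverField
    paez: AEZMap


def assemble_features(drivers: DriverStack, aez: AEZMap
                      ) -> tuple[FeatureTable, np.ndarray, int]:
    """One row per land cell with complete data.

    Returns the table, the flat cell indices its rows map to, and the count
    of land cells excluded for missing values.  The AEZ and soil alphabets
    are declared from the zone legend and the soil-class alphabet so that
    projected tables validate against the same schema.
    """
    grid = drivers.grid
    if not grid.same_geometry(aez.grid):
        raise ValueError("AEZ map grid does not match driver grid")
    if drivers.aez is None:
        drivers = drivers.with_aez(aez.zone_id)
    layers = {
        "mean_annual_temp": drivers.mean_annual_temp,
        "mean_annual_precip": drivers.mean_annual_precip,
        "aez": drivers.aez,
        "gdp_regional": drivers.gdp_regional,
        "n_fert": drivers.n_fert,
        "p_fert": drivers.p_fert,
        "soil_class": drivers.soil_class,
        "elevation": drivers.elevation,
    }
    flat = {k: np.asarray(v, dtype=float).ravel() for k, v in layers.items()}
    land = grid.land_mask.ravel()
    complete = land.copy()
    for v in flat.values():
        complete &= np.isfinite(v)
    n_excluded = int(land.sum() - complete.sum())
    rows = np.nonzero(complete)[0]
    X = np.column_stack([flat[name][rows] for name, _ in FEATURE_COLUMNS])
    names = [name for name, _ in FEATURE_COLUMNS]
    cat = np.array([is_cat for _, is_cat in FEATURE_COLUMNS])
    n_thermal = 3
    zone_alphabet = np.arange(1 + n_thermal * aez.thresholds.n_moisture, dtype=float)
    categories = {
        names.index("aez"): zone_alphabet,
        names.index("soil_class"): np.arange(drivers.n_soils, dtype=float),
    }
    table = FeatureTable(X, np.zeros(len(rows)), names, cat, categories)
    return table, rows, n_excluded


def _with_response(table: FeatureTable, y: np.ndarray) -> FeatureTable:
    return FeatureTable(table.X, y, table.columns, table.categorical,
                        table.categories)


def train_baseline(features: FeatureTable, cover: np.ndarray,
                   protocol: TrainingProtocol) -> FittedModel:
    """Train the pooled ensemble with the iterated-subsample protocol.

    Per iteration: draw ``cells_per_iteration`` distinct rows, split them
    70/30, fit one tree on a bootstrap of the training part, and record the
    holdout MSE/R² on the test part.  The pooled trees keep their global
    bootstrap row indices so the ensemble's OOB error over the full table is
    also computed.
    """
    y = np.asarray(cover, dtype=float)
    table = _with_response(features, y)
    n = table.n
    proto = protocol
    if proto.cells_per_iteration > n:
        raise ValueError(
            f"cells_per_iteration={proto.cells_per_iteration} exceeds the "
            f"{n} available rows"
        )
    mtry = proto.mtry if proto.mtry is not None else default_mtry(table.p)
    ss = np.random.SeedSequence(proto.seed)
    children = ss.spawn(proto.n_iterations)
    trees, boots = [], []
    hold_r2 = np.empty(proto.n_iterations)
    hold_mse = np.empty(proto.n_iterations)
    for it in range(proto.n_iterations):
        rng = np.random.default_rng(children[it])
        cells = rng.choice(n, size=proto.cells_per_iteration, replace=False)
        n_train = int(round(proto.train_fraction * proto.cells_per_iteration))
        train_rows = cells[:n_train]
        test_rows = cells[n_train:]
        boot = rng.choice(train_rows, size=n_train, replace=True)
        tree = fit_tree(table, boot, mtry, proto.min_leaf, rng)
        pred = tree.predict(table.X[test_rows], table.categorical)
        resid = y[test_rows] - pred
        mse = float(np.mean(resid**2))
        var = float(np.var(y[test_rows]))
        hold_mse[it] = mse
        hold_r2[it] = 1.0 - mse / var if var > 0 else np.nan
        trees.append(tree)
        boots.append(boot)
    forest = Forest(trees, boots, n, mtry, proto.min_leaf, proto.seed,
                    table.categorical.copy(), list(table.columns))
    oob = oob_error(forest, table)
    return FittedModel(forest, hold_r2, hold_mse, oob.mse, oob.r2,
                       table.schema(), proto)


def _check_schema(model: FittedModel, table: FeatureTable) -> None:
    got = table.schema()
    want = model.schema
    if got["columns"] != want["columns"] or got["categorical"] != want["categorical"]:
        raise ValueError("feature schema drift between training and projection")


def predict_cover(model: FittedModel, drivers: DriverStack,
                  aez: AEZMap) -> CoverField:
    """Bagged prediction on a driver stack, clamped into [0, 1] and mapped
    back onto the grid (NoData propagated)."""
    table, rows, _ = assemble_features(drivers, aez)
    _check_schema(model, table)
    raw = predict(model.forest, table.X)
    clamped = np.clip(raw, 0.0, 1.0)
    flat = np.full(drivers.grid.n_lat * drivers.grid.n_lon, np.nan)
    flat[rows] = clamped
    return CoverField(drivers.grid, flat.reshape(drivers.grid.shape))


def project_scenario(model: FittedModel, drivers_future: DriverStack,
                     paez: AEZMap,
                     scenario: ScenarioSpec | str = "scenario") -> ScenarioProjection:
    """Project cover for one scenario: future annual means + PAEZ in the
    features, static layers at baseline, predictions clamped into [0, 1]."""
    name = scenario.name if isinstance(scenario, ScenarioSpec) else str(scenario)
    drivers_future = drivers_future.with_aez(paez.zone_id)
    cover = predict_cover(model, drivers_future, paez)
    return ScenarioProjection(name, cover, paez)
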