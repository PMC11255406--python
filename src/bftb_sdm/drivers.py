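"""Environmental driver-importance analysis of the richness pattern.

Three complementary analyses over a per-cell table of 13 candidate drivers:

* random-forest classification of hotspot vs non-hotspot cells, importance
  as mean decrease Gini (MDG);
* random-forest regression of richness, importance as increase in node
  purity (INP);
* single-variable Gaussian GLMs of richness, importance as adjusted R².

The 13 drivers fall into five groups reflecting the water-energy dynamics,
habitat heterogeneity, historical climate stability and human-interference
hypotheses.  The temperature and precipitation variables also feed the
per-species SDMs, so importance rankings flag them as a separate block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .raster import RasterGrid
from .stacking import HotspotMask, RichnessMap

__all__ = [
    "DRIVER_GROUPS",
    "DRIVER_VARIABLES",
    "SDM_MODELLING_VARIABLES",
    "DriverTable",
    "ImportanceReport",
    "assemble_driver_table",
    "rf_hotspot_classifier",
    "rf_richness_regression",
    "glm_per_variable",
    "rank_importance",
]

log = logging.getLogger(__name__)

#: Five driver groups; the default registry is a synthetic reconstruction
#: of the usual candidates (TANO/PANO are the temperature and precipitation
#: anomalies since the Last Glacial Maximum).
DRIVER_GROUPS: dict[str, tuple[str, ...]] = {
    "temperature": ("annual_temp", "tmin_cold", "temp_seasonality"),
    "precipitation": ("annual_precip", "precip_dry_month", "precip_seasonality"),
    "habitat_heterogeneity": ("elev_range", "surface_roughness", "habitat_div"),
    "historical_anomaly": ("tano", "pano"),
    "human_interference": ("pop_density", "built_up"),
}

#: Registry order — column order of every DriverTable.
DRIVER_VARIABLES: tuple[str, ...] = tuple(
    v for group in DRIVER_GROUPS.values() for v in group
)

#: Variables also used inside the per-species SDMs (temperature +
#: precipitation groups); ranked as a separate block in reports.
SDM_MODELLING_VARIABLES: frozenset[str] = frozenset(
    DRIVER_GROUPS["temperature"] + DRIVER_GROUPS["precipitation"]
)


@dataclass
class DriverTable:
    """One row per complete land cell: 13 drivers + richness + hotspot."""

    data: pd.DataFrame
    variables: tuple[str, ...] = DRIVER_VARIABLES

    def __post_init__(self) -> None:
        missing = [v for v in self.variables if v not in self.data.columns]
        if missing:
            raise ValueError(f"driver table lacks variable column(s) {missing}")
        for col in ("richness", "hotspot"):
            if col not in self.data.columns:
                raise ValueError(f"driver table lacks {col!r} column")

    @property
    def X(self) -> pd.DataFrame:
        return self.data[list(self.variables)]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ImportanceReport:
    """Per-variable importances and model metrics from one analysis."""

    measure: str  # "mdg" | "inp" | "glm_adj_r2"
    importance: pd.Series  # indexed by variable name
    metrics: dict[str, float] = field(default_factory=dict)


def assemble_driver_table(
    layers: dict[str, RasterGrid] | list[RasterGrid],
    richness: RichnessMap,
    hotspots: HotspotMask,
    variables: tuple[str, ...] = DRIVER_VARIABLES,
) -> DriverTable:
    """Join driver layers, richness and hotspot label into a per-cell table.

    Rows are land cells with complete (non-nodata) data in every layer;
    the dropped-cell count is logged.  Fewer than 13 layers is tolerated
    with a warning when a reduced ``variables`` registry is passed.
    """
    if isinstance(layers, list):
        layers = {r.name: r for r in layers}
    missing = [v for v in variables if v not in layers]
    if missing:
        raise ValueError(f"missing driver layer(s): {missing}")
    if len(variables) < len(DRIVER_VARIABLES):
        log.warning("driver registry reduced to %d variables", len(variables))
    grid = richness.grid
    cols = {}
    valid = np.isfinite(richness.richness.values.ravel())
    for v in variables:
        layer = layers[v]
        if layer.grid != grid:
            raise ValueError(f"layer {v} not on the richness grid")
        flat = layer.values.ravel()
        cols[v] = flat
        valid &= np.isfinite(flat)
    n_land = int(np.isfinite(richness.richness.values).sum())
    idx = np.flatnonzero(valid)
    data = pd.DataFrame({v: cols[v][idx] for v in variables})
    data["richness"] = richness.richness.values.ravel()[idx].astype(int)
    data["hotspot"] = hotspots.mask.values.ravel()[idx] > 0
    data["cell_index"] = idx
    log.info(
        "driver table: %d rows (%d incomplete land cells dropped)",
        len(data), n_land - len(data),
    )
    return DriverTable(data=data, variables=tuple(variables))


def rf_hotspot_classifier(
    table: DriverTable,
    mtry: int = 7,
    ntree: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
) -> ImportanceReport:
    """Random-forest hotspot/non-hotspot classifier with MDG importance.

    A stratified ``train_frac`` split trains the forest (out-of-bag error
    from the training data); the held-out cells give a test AUC.
    """
    y = table.data["hotspot"].to_numpy()
    if y.all() or not y.any():
        raise ValueError("need both hotspot and non-hotspot cells")
    X = table.X.to_numpy()
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=seed
    )
    rf = RandomForestClassifier(
        n_estimators=ntree,
        max_features=min(mtry, X.shape[1]),
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(Xtr, ytr)
    auc = float(roc_auc_score(yte, rf.predict_proba(Xte)[:, 1]))
    oob_error = 1.0 - float(rf.oob_score_)
    return ImportanceReport(
        measure="mdg",
        importance=pd.Series(rf.feature_importances_, index=list(table.variables)),
        metrics={"oob_error": oob_error, "test_auc": auc},
    )


def rf_richness_regression(
    table: DriverTable,
    mtry: int = 8,
    ntree: int = 1000,
    seed: int = 0,
) -> ImportanceReport:
    """Random-forest richness regression with node-purity (INP) importance.

    Fit quality is the out-of-bag R² of the forest.
    """
    y = table.data["richness"].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("richness response is constant")
    X = table.X.to_numpy()
    rf = RandomForestRegressor(
        n_estimators=ntree,
        max_features=min(mtry, X.shape[1]),
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return ImportanceReport(
        measure="inp",
        importance=pd.Series(rf.feature_importances_, index=list(table.variables)),
        metrics={"oob_r2": float(rf.oob_score_)},
    )


def glm_per_variable(table: DriverTable, family: str = "gaussian") -> ImportanceReport:
    """Single-variable GLMs of richness; importance = adjusted R².

    With the default Gaussian identity link each fit is ordinary least
    squares and adjusted R² = 1 - (1-R²)(n-1)/(n-2); negative values are
    reported as computed.  A zero-variance driver gets adjusted R² = 0 and
    a ``degenerate`` note.  ``family="poisson"`` swaps in a log-link
    Poisson GLM whose importance is 1 - deviance/null-deviance.
    """
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 rows")
    y = table.data["richness"].to_numpy(float)
    vals = {}
    degenerate = []
    for v in table.variables:
        x = table.data[v].to_numpy(float)
        if np.ptp(x) == 0:
            vals[v] = 0.0
            degenerate.append(v)
            continue
        X = sm.add_constant(x)
        if family == "gaussian":
            res = sm.OLS(y, X).fit()
            r2 = float(res.rsquared)
            vals[v] = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        elif family == "poisson":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            vals[v] = 1.0 - float(res.deviance / res.null_deviance)
        else:
            raise ValueError(f"unknown GLM family {family!r}")
    if degenerate:
        log.warning("zero-variance driver(s) %s: adjusted R² set to 0", degenerate)
    return ImportanceReport(
        measure="glm_adj_r2",
        importance=pd.Series(vals, index=list(table.variables)),
        metrics={"n_degenerate": float(len(degenerate))},
    )


def rank_importance(reports: list[ImportanceReport]) -> pd.DataFrame:
    """Cross-analysis comparison table of importances and ranks.

    One row per variable with each measure's value and rank (1 = most
    important) plus its driver group and whether it is also an SDM
    modelling variable (temperature/precipitation block).
    """
    if not reports:
        raise ValueError("no reports given")
    variables = list(reports[0].importance.index)
    out = pd.DataFrame({"variable": variables})
    group_of = {v: g for g, vs in DRIVER_GROUPS.items() for v in vs}
    out["group"] = [group_of.get(v, "other") for v in variables]
    out["sdm_modelling"] = [v in SDM_MODELLING_VARIABLES for v in variables]
    for rep in reports:
        out[rep.measure] = rep.importance.reindex(variables).to_numpy()
        out[f"{rep.measure}_rank"] = (
            out[rep.measure].rank(ascending=False, method="min").astype(int)
        )
    return out


def plot_importance(ranked: pd.DataFrame, path=None):
    """Bar-plot of MDG/INP with adjusted-R² points, one bar group per driver."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4.5))
    x = np.arange(len(ranked))
    width = 0.35
    if "mdg" in ranked:
        ax.bar(x - width / 2, ranked["mdg"], width, label="MDG (classification)")
    if "inp" in ranked:
        ax.bar(x + width / 2, ranked["inp"], width, label="INP (regression)", hatch="//")
    ax.set_ylabel("random-forest importance")
    ax.set_xticks(x)
    ax.set_xticklabels(ranked["variable"], rotation=60, ha="right")
    if "glm_adj_r2" in ranked:
        ax2 = ax.twinx()
        ax2.plot(x, ranked["glm_adj_r2"], "ko-", label="GLM adjusted $R^2$")
        ax2.set_ylabel("adjusted $R^2$")
    ax.legend(loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
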