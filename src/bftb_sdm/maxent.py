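"""Presence-background maximum-entropy SDM (MaxEnt-style), reimplemented.

The model is a Gibbs distribution over background cells,
``P(x) = exp(lambda . f(x)) / Z``, fitted by maximizing the L1-penalized
log-likelihood

    L(lambda) = mean_presence[lambda . f(x)] - log Z(lambda)
                - sum_j beta_j |lambda_j|,

with ``Z`` summed over background and per-feature penalties ``beta_j``
scaled by the regularization multiplier (RM) and the published per-class
sample-size interpolation tables.  Feature classes are the classic linear
(L), quadratic (Q), hinge (H), product (P) and threshold (T) transforms of
min-max standardized variables, all mapped to [0, 1] and clamped.

The convex optimum is found with L-BFGS-B on the positive/negative split
``lambda = lambda+ - lambda-`` (both >= 0), which makes the penalty smooth.
Model selection follows the ENMeval recipe: AICc over a feature-class x RM
grid with the raw likelihood normalized over the study cells and k = the
number of nonzero coefficients.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .occurrences import OccurrenceSet
from .raster import RasterGrid

__all__ = [
    "FeatureSet",
    "MaxEntModel",
    "TunedSDM",
    "DEFAULT_FC_GRID",
    "DEFAULT_RM_GRID",
    "expand_features",
    "fit_maxent",
    "predict_raw",
    "predict_logistic",
    "compute_aicc",
    "tune_maxent",
    "run_replicates",
    "evaluate_auc",
    "compute_thresholds",
    "extract_region_env",
    "env_at_points",
]

log = logging.getLogger(__name__)

DEFAULT_FC_GRID: tuple[str, ...] = ("L", "H", "LQ", "LQH", "LQHP", "LQHPT")
DEFAULT_RM_GRID: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

# Published per-class regularization tables: sample sizes -> base beta,
# linearly interpolated in the number of presences and clamped at the ends.
_BETA_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "L": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "Q": ((0, 10, 17, 30, 100), (1.3, 1.3, 0.8, 0.5, 0.25)),
    "P": ((0, 10, 17, 30, 100), (2.6, 2.6, 1.6, 0.67, 0.26)),
    "T": ((0, 100), (2.0, 1.0)),
    "H": ((0.0,), (0.5,)),
}

_VALID_CLASSES = frozenset("LQHPT")


@dataclass
class FeatureSet:
    """Feature definitions plus background standardization constants.

    ``descriptors`` holds one tuple per feature:
    ``("L", j)``, ``("Q", j)``, ``("P", i, j)``,
    ``("T", j, knot)``, ``("H", j, knot, "fwd"|"rev")`` —
    indices into ``variables``, knots on the standardized [0, 1] scale.
    """

    variables: tuple[str, ...]
    classes: tuple[str, ...]
    mins: np.ndarray = field(repr=False)
    maxs: np.ndarray = field(repr=False)
    descriptors: list[tuple] = field(default_factory=list, repr=False)

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def feature_classes(self) -> np.ndarray:
        """Class letter of each feature (for regularization weights)."""
        return np.array([d[0] for d in self.descriptors])

    def standardize(self, env: np.ndarray) -> np.ndarray:
        """Min-max standardize and clamp to [0, 1] (MaxEnt-style clamping)."""
        env = np.asarray(env, float)
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        return np.clip((env - self.mins) / span, 0.0, 1.0)

    def transform(self, env: np.ndarray) -> np.ndarray:
        """Feature matrix (n, n_features) for an (n, n_vars) env matrix."""
        z = self.standardize(env)
        cols = np.empty((z.shape[0], self.n_features))
        for k, d in enumerate(self.descriptors):
            kind = d[0]
            if kind == "L":
                cols[:, k] = z[:, d[1]]
            elif kind == "Q":
                cols[:, k] = z[:, d[1]] ** 2
            elif kind == "P":
                cols[:, k] = z[:, d[1]] * z[:, d[2]]
            elif kind == "T":
                cols[:, k] = (z[:, d[1]] >= d[2]).astype(float)
            elif kind == "H":
                _, j, knot, side = d
                if side == "fwd":
                    cols[:, k] = np.maximum(0.0, z[:, j] - knot) / (1.0 - knot)
                else:
                    cols[:, k] = np.maximum(0.0, knot - z[:, j]) / knot
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {kind!r}")
        return cols


def expand_features(
    values: np.ndarray,
    classes: str | set[str] = "LQ",
    knots_per_var: int = 10,
    background_rows: np.ndarray | None = None,
    variable_names: tuple[str, ...] | None = None,
) -> tuple[FeatureSet, np.ndarray]:
    """Build a FeatureSet from an env matrix and return its feature matrix.

    Standardization constants and knot locations (uniform quantiles of the
    background distribution) come from ``background_rows`` (default: all
    rows).  Variables constant on the background contribute no features and
    trigger a warning.
    """
    values = np.atleast_2d(np.asarray(values, float))
    classes = set(classes)
    bad = classes - _VALID_CLASSES
    if bad:
        raise ValueError(f"unknown feature class(es) {sorted(bad)}")
    if values.shape[1] < 1:
        raise ValueError("need at least one variable")
    if ("H" in classes or "T" in classes) and knots_per_var < 1:
        raise ValueError("knots_per_var must be >= 1 for hinge/threshold features")
    bg = values if background_rows is None else values[background_rows]
    mins = bg.min(axis=0)
    maxs = bg.max(axis=0)
    d = values.shape[1]
    names = variable_names or tuple(f"var{j}" for j in range(d))
    active = [j for j in range(d) if maxs[j] > mins[j]]
    dropped = [names[j] for j in range(d) if maxs[j] == mins[j]]
    if dropped:
        log.warning("constant variable(s) %s: features dropped", dropped)

    fs = FeatureSet(variables=tuple(names), classes=tuple(sorted(classes)), mins=mins, maxs=maxs)
    zbg = fs.standardize(bg)
    quantiles = (np.arange(1, knots_per_var + 1)) / (knots_per_var + 1)
    descriptors: list[tuple] = []
    if "L" in classes:
        descriptors += [("L", j) for j in active]
    if "Q" in classes:
        descriptors += [("Q", j) for j in active]
    if "P" in classes:
        descriptors += [("P", i, j) for a, i in enumerate(active) for j in active[a + 1:]]
    if "H" in classes:
        for j in active:
            for knot in np.unique(np.quantile(zbg[:, j], quantiles)):
                if knot < 1.0:
                    descriptors.append(("H", j, float(knot), "fwd"))
                if knot > 0.0:
                    descriptors.append(("H", j, float(knot), "rev"))
    if "T" in classes:
        for j in active:
            for knot in np.unique(np.quantile(zbg[:, j], quantiles)):
                if 0.0 < knot <= 1.0:
                    descriptors.append(("T", j, float(knot)))
    fs.descriptors = descriptors
    return fs, fs.transform(values)


@dataclass
class MaxEntModel:
    """A fitted penalized maximum-entropy model."""

    features: FeatureSet
    lambdas: np.ndarray = field(repr=False)
    rm: float = 1.0
    beta: np.ndarray = field(default=None, repr=False)
    log_partition: float = 0.0  # log Z over the training background
    entropy: float = 0.0  # entropy of the fitted raw distribution
    converged: bool = True

    @property
    def n_params(self) -> int:
        """Number of nonzero coefficients (AICc parameter count)."""
        return int(np.sum(np.abs(self.lambdas) > 1e-8))

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "variables": list(self.features.variables),
            "classes": list(self.features.classes),
            "mins": self.features.mins.tolist(),
            "maxs": self.features.maxs.tolist(),
            "descriptors": [list(d) for d in self.features.descriptors],
            "lambdas": self.lambdas.tolist(),
            "rm": self.rm,
            "log_partition": self.log_partition,
            "entropy": self.entropy,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path


def _default_betas(features: FeatureSet, n_presence: int, rm: float, presence_F: np.ndarray) -> np.ndarray:
    """Per-feature L1 weights: rm x class table(m) x sd_j / sqrt(m)."""
    m = max(n_presence, 1)
    sd = presence_F.std(axis=0)
    sd = np.maximum(sd, 0.05)  # floor keeps rarely-varying features penalized
    classes = features.feature_classes()
    base = np.empty(features.n_features)
    for letter, (ts, bs) in _BETA_TABLES.items():
        sel = classes == letter
        if sel.any():
            base[sel] = np.interp(m, ts, bs)
    return rm * base * sd / math.sqrt(m)


def fit_maxent(
    presence_idx: np.ndarray,
    background_idx: np.ndarray,
    feature_matrix: np.ndarray,
    rm: float = 1.0,
    features: FeatureSet | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    trace: list[float] | None = None,
) -> MaxEntModel:
    """Fit the L1-penalized maximum-entropy model.

    ``feature_matrix`` holds all rows; ``presence_idx`` / ``background_idx``
    select presences and background.  Deterministic given inputs.  A fit
    that exhausts ``max_iter`` without meeting the gradient tolerance is
    returned with ``converged=False`` (callers treat it as a failed
    replicate).  ``trace``, when given, collects the penalized objective
    (to be maximized) at each iterate.
    """
    F = np.asarray(feature_matrix, float)
    presence_idx = np.asarray(presence_idx, int)
    background_idx = np.asarray(background_idx, int)
    if presence_idx.size < 1:
        raise ValueError("need at least one presence")
    if background_idx.size < 1:
        raise ValueError("need background cells")
    Fp = F[presence_idx]
    Fb = F[background_idx]
    p = F.shape[1]
    mp = Fp.mean(axis=0)
    if features is None:
        features = FeatureSet(
            variables=tuple(f"var{j}" for j in range(p)),
            classes=("L",),
            mins=np.zeros(p),
            maxs=np.ones(p),
            descriptors=[("L", j) for j in range(p)],
        )
    beta = _default_betas(features, presence_idx.size, rm, Fp)

    if p == 0:  # all features dropped (e.g. constant layers): uniform model
        nb = background_idx.size
        return MaxEntModel(
            features=features,
            lambdas=np.empty(0),
            rm=rm,
            beta=beta,
            log_partition=math.log(nb),
            entropy=math.log(nb),
            converged=True,
        )

    def objective(u: np.ndarray):
        lam = u[:p] - u[p:]
        scores = Fb @ lam
        logz = logsumexp(scores)
        q = np.exp(scores - logz)
        g_lam = -(mp - q @ Fb)
        f = -(mp @ lam - logz) + beta @ (u[:p] + u[p:])
        grad = np.concatenate([g_lam + beta, -g_lam + beta])
        return f, grad

    callback = None
    if trace is not None:
        trace.append(-objective(np.zeros(2 * p))[0])
        callback = lambda u: trace.append(-objective(u)[0])  # noqa: E731
    res = minimize(
        objective,
        np.zeros(2 * p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * p),
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
        callback=callback,
    )
    lam = res.x[:p] - res.x[p:]
    scores = Fb @ lam
    logz = float(logsumexp(scores))
    q = np.exp(scores - logz)
    entropy = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())
    return MaxEntModel(
        features=features,
        lambdas=lam,
        rm=rm,
        beta=beta,
        log_partition=logz,
        entropy=entropy,
        converged=bool(res.success or res.status == 0),
    )


def predict_raw(model: MaxEntModel, feature_matrix: np.ndarray) -> np.ndarray:
    """Raw (Gibbs) score exp(lambda . f(x)) / Z per row."""
    scores = np.asarray(feature_matrix, float) @ model.lambdas
    return np.exp(scores - model.log_partition)


def predict_logistic(model: MaxEntModel, feature_matrix: np.ndarray) -> np.ndarray:
    """Logistic-output suitability in (0, 1).

    The classic transform ``c*raw / (1 + c*raw)`` with ``c = exp(H)``, so a
    cell with an average raw score maps to a suitability set by the fitted
    distribution's entropy H; strictly increasing in the raw score.
    """
    raw = predict_raw(model, feature_matrix)
    c = np.exp(model.entropy)
    return c * raw / (1.0 + c * raw)


def compute_aicc(
    model: MaxEntModel,
    presence_features: np.ndarray,
    study_features: np.ndarray,
) -> float:
    """Small-sample AIC of the model's raw likelihood.

    The raw distribution is renormalized over the study cells; k counts
    nonzero coefficients only.  Returns +inf when n_presences <= k + 1.
    """
    n = np.atleast_2d(presence_features).shape[0]
    k = model.n_params
    if n - k - 1 <= 0:
        return float("inf")
    study_scores = np.asarray(study_features, float) @ model.lambdas
    logz = logsumexp(study_scores)
    lnl = float((np.atleast_2d(presence_features) @ model.lambdas - logz).sum())
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


def evaluate_auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    sp = np.asarray(scores_presence, float)
    sb = np.asarray(scores_background, float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2
    return float(u / (sp.size * sb.size))


def compute_thresholds(training_suitabilities: np.ndarray) -> tuple[float, float]:
    """Minimum training presence (MTP) and 10th-percentile (P10) thresholds.

    P10 uses the order-statistic convention: the ceil(0.1 n)-th smallest
    training suitability, so at least 90% of training values are >= P10.
    """
    vals = np.sort(np.asarray(training_suitabilities, float))
    if vals.size < 1:
        raise ValueError("need at least one training suitability")
    mtp = float(vals[0])
    k = math.ceil(0.1 * vals.size)
    p10 = float(vals[max(k - 1, 0)])
    return mtp, p10


# ---------------------------------------------------------------------------
# raster-facing helpers: environmental extraction, tuning and replicates
# ---------------------------------------------------------------------------


def _region_mask_array(region) -> np.ndarray:
    """Accept a CalibrationRegion, RasterGrid or boolean array."""
    if hasattr(region, "region_mask"):
        region = region.region_mask
    if isinstance(region, RasterGrid):
        return region.values > 0
    return np.asarray(region, bool)


def extract_region_env(
    layers: dict[str, RasterGrid],
    variable_names: tuple[str, ...],
    region,
    max_background: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Environment matrix of region cells (optionally subsampled).

    Returns ``(env, flat_cell_indices)``; when the region exceeds
    ``max_background`` cells a seeded uniform sample is drawn.
    """
    mask = _region_mask_array(region)
    for v in variable_names:
        mask &= np.isfinite(layers[v].values)
    idx = np.flatnonzero(mask.ravel())
    if idx.size > max_background:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_background, replace=False))
    env = np.column_stack([layers[v].values.ravel()[idx] for v in variable_names])
    return env, idx


def env_at_points(
    layers: dict[str, RasterGrid],
    variable_names: tuple[str, ...],
    coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Environment matrix at point coordinates; returns (env, flat indices)."""
    grid = layers[variable_names[0]].grid
    cells = np.array([grid.cell_of(lon, lat) for lon, lat in np.asarray(coords, float)])
    flat = cells[:, 0] * grid.ncols + cells[:, 1]
    env = np.column_stack([layers[v].values.ravel()[flat] for v in variable_names])
    return env, flat


@dataclass
class TunedSDM:
    """Tuning + replicate results for one MaxEnt-tier species."""

    species: str
    best_fc: str
    best_rm: float
    tuning_table: pd.DataFrame = field(repr=False)
    replicate_aucs: list[float] = field(default_factory=list)
    mean_test_auc: float = float("nan")
    suitability: RasterGrid | None = field(default=None, repr=False)
    mtp_threshold: float = float("nan")
    p10_threshold: float = float("nan")
    success: bool = False
    model: MaxEntModel | None = field(default=None, repr=False)


def tune_maxent(
    occ: OccurrenceSet,
    layers: dict[str, RasterGrid],
    region,
    variable_names: tuple[str, ...],
    fc_grid: tuple[str, ...] = DEFAULT_FC_GRID,
    rm_grid: tuple[float, ...] = DEFAULT_RM_GRID,
    knots_per_var: int = 10,
    max_background: int = 10_000,
    seed: int = 0,
) -> tuple[str, float, pd.DataFrame]:
    """Select (feature class, RM) by minimum AICc over the full grid.

    All grid cells are fitted on the full presence set; ties go to fewer
    parameters, then lower RM, then the simpler feature class (grid order).
    Returns ``(best_fc, best_rm, table)`` with per-cell AICc and delta-AICc.
    Raises ``RuntimeError`` if every fit fails (callers fall back to MCP-AT).
    """
    coords = occ.coords
    if len(coords) < 5:
        raise ValueError("MaxEnt tier requires >= 5 occurrences")
    bg_env, bg_idx = extract_region_env(layers, variable_names, region, max_background, seed)
    pr_env, _ = env_at_points(layers, variable_names, coords)
    ok = np.all(np.isfinite(pr_env), axis=1)
    pr_env = pr_env[ok]
    if len(pr_env) < 5:
        raise RuntimeError("fewer than 5 presences with valid environment")
    rows = []
    best_key = None
    best = None
    for fci, fc in enumerate(fc_grid):
        env_all = np.vstack([bg_env, pr_env])
        background_rows = np.arange(len(bg_env))
        presence_rows = np.arange(len(bg_env), len(env_all))
        fs, F = expand_features(
            env_all, set(fc), knots_per_var,
            background_rows=background_rows, variable_names=variable_names,
        )
        for rm in rm_grid:
            model = fit_maxent(presence_rows, background_rows, F, rm, features=fs)
            aicc = (
                compute_aicc(model, F[presence_rows], F[background_rows])
                if model.converged
                else float("inf")
            )
            rows.append(
                {"fc": fc, "rm": rm, "aicc": aicc, "n_params": model.n_params,
                 "converged": model.converged}
            )
            key = (aicc, model.n_params, rm, fci)
            if math.isfinite(aicc) and (best_key is None or key < best_key):
                best_key = key
                best = (fc, rm)
    table = pd.DataFrame(rows)
    finite = table["aicc"][np.isfinite(table["aicc"])]
    table["delta_aicc"] = table["aicc"] - (finite.min() if len(finite) else float("nan"))
    if best is None:
        raise RuntimeError(f"{occ.species}: all tuning fits failed")
    return best[0], best[1], table


def run_replicates(
    occ: OccurrenceSet,
    layers: dict[str, RasterGrid],
    region,
    variable_names: tuple[str, ...],
    fc: str,
    rm: float,
    n_rep: int = 10,
    train_frac: float = 0.8,
    knots_per_var: int = 10,
    max_background: int = 10_000,
    seed: int = 0,
    auc_gate: float = 0.8,
) -> TunedSDM:
    """Bootstrap-style replicate evaluation and mean suitability map.

    Each replicate draws a seeded random ``train_frac`` presence split,
    fits on the training presences and scores test presences against the
    background (rank AUC).  The suitability raster is the cellwise mean of
    the replicate logistic maps over region cells (NaN outside).  Success
    requires mean test AUC >= ``auc_gate``.
    """
    coords = occ.coords
    if len(coords) < 5:
        raise ValueError("MaxEnt tier requires >= 5 occurrences")
    bg_env, bg_idx = extract_region_env(layers, variable_names, region, max_background, seed)
    pr_env, _ = env_at_points(layers, variable_names, coords)
    pr_env = pr_env[np.all(np.isfinite(pr_env), axis=1)]
    n = len(pr_env)
    env_all = np.vstack([bg_env, pr_env])
    background_rows = np.arange(len(bg_env))
    presence_rows = np.arange(len(bg_env), len(env_all))
    fs, F = expand_features(
        env_all, set(fc), knots_per_var,
        background_rows=background_rows, variable_names=variable_names,
    )
    rng = np.random.default_rng(seed)
    n_train = max(int(round(train_frac * n)), 1)
    aucs: list[float] = []
    maps: list[np.ndarray] = []
    train_suits: list[np.ndarray] = []
    last_model = None
    for _ in range(n_rep):
        perm = rng.permutation(n)
        train = presence_rows[perm[:n_train]]
        test = presence_rows[perm[n_train:]]
        if test.size < 1:
            log.warning("%s: replicate skipped (no test presences)", occ.species)
            continue
        model = fit_maxent(train, background_rows, F, rm, features=fs)
        if not model.converged:
            log.warning("%s: replicate failed to converge", occ.species)
            continue
        auc = evaluate_auc(predict_raw(model, F[test]), predict_raw(model, F[background_rows]))
        aucs.append(auc)
        maps.append(predict_logistic(model, F[background_rows]))
        train_suits.append(predict_logistic(model, F[train]))
        last_model = model
    mean_auc = float(np.mean(aucs)) if aucs else float("nan")

    grid = layers[variable_names[0]].grid
    suit_vals = np.full(grid.nrows * grid.ncols, np.nan)
    if maps:
        suit_vals[bg_idx] = np.mean(maps, axis=0)
    suitability = RasterGrid(
        name=f"{occ.species}_suitability", grid=grid,
        values=suit_vals.reshape(grid.shape),
    )
    if train_suits:
        mtp, p10 = compute_thresholds(np.concatenate(train_suits))
    else:
        mtp = p10 = float("nan")
    return TunedSDM(
        species=occ.species,
        best_fc=fc,
        best_rm=rm,
        tuning_table=pd.DataFrame(),
        replicate_aucs=aucs,
        mean_test_auc=mean_auc,
        suitability=suitability,
        mtp_threshold=mtp,
        p10_threshold=p10,
        success=bool(aucs) and mean_auc >= auc_gate,
        model=last_model,
    )
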