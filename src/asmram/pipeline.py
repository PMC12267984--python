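"""Peak-RAM regression pipeline: screen, cross-validate, tune, fit, calibrate.

The pipeline is trained once per assembler parameter setting ("default" or
"meta-sensitive") on a table of per-dataset features plus the observed peak
RAM in GB, and produces a :class:`ModelBundle` whose predictions carry a
non-negative calibration bias that guards against under-allocation.
"""

from __future__ import annotations

import io as _io
import itertools
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesRegressor,
    RandomForestRegressor,
    VotingRegressor,
)
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

TARGET_COLUMN = "observed_peak_ram_gb"
MODES = ("default", "meta-sensitive")
BUNDLE_FORMAT_VERSION = 1

__all__ = [
    "TARGET_COLUMN",
    "TrainingTable",
    "ScreenReport",
    "CVReport",
    "ModelBundle",
    "BundleFormatError",
    "default_families",
    "make_family",
    "screen_features_by_correlation",
    "crossvalidate_families",
    "select_family",
    "grid_search",
    "prune_features_by_importance",
    "calibrate_bias",
    "fit_final_model",
    "save_bundle",
    "load_bundle",
]


class BundleFormatError(RuntimeError):
    """Raised when a model bundle file cannot be understood."""


@dataclass
class TrainingTable:
    """Per-dataset features plus the observed peak RAM, for one assembler mode."""

    frame: pd.DataFrame  # indexed by dataset_id; feature columns + target
    mode: str = "default"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if TARGET_COLUMN not in self.frame.columns:
            raise ValueError(f"training table lacks target column {TARGET_COLUMN!r}")
        if self.frame.index.duplicated().any():
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicated dataset ids: {dupes}")
        if (self.frame[TARGET_COLUMN] <= 0).any():
            raise ValueError("observed_peak_ram_gb must be > 0 for every row")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != TARGET_COLUMN]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def features(self, names: Optional[Sequence[str]] = None) -> pd.DataFrame:
        cols = list(names) if names is not None else self.feature_columns
        unknown = [c for c in cols if c not in self.frame.columns]
        if unknown:
            raise KeyError(f"unknown feature column(s): {unknown}")
        return self.frame[cols]

    @property
    def target(self) -> pd.Series:
        return self.frame[TARGET_COLUMN]


@dataclass
class ScreenReport:
    """Pearson screening result: one row per feature (r, p_value, retained)."""

    frame: pd.DataFrame
    r_min: float
    p_max: float
    absolute: bool = False

    @property
    def retained(self) -> list[str]:
        return self.frame.index[self.frame["retained"]].tolist()

    @property
    def dropped(self) -> list[str]:
        return self.frame.index[~self.frame["retained"]].tolist()


@dataclass
class CVReport:
    """Per-family cross-validated RMSE summary over one shared fold partition."""

    frame: pd.DataFrame  # index family, columns mean_rmse_gb, sd_rmse_gb
    k_folds: int
    seed: int
    fold_assignment: np.ndarray = field(repr=False, default=None)

    @property
    def families(self) -> list[str]:
        return self.frame.index.tolist()


def make_family(name: str, seed: int = 0, n_estimators: int = 100, **params):
    """Instantiate a regressor family by name."""
    if name == "linear":
        return LinearRegression(**params)
    if name == "svm":
        return make_pipeline(StandardScaler(), SVR(**params))
    if name == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestRegressor(random_state=seed, n_estimators=n_estimators, **params)
    if name == "extra_trees":
        return ExtraTreesRegressor(random_state=seed, n_estimators=n_estimators, **params)
    if name == "voting":
        return VotingRegressor(
            estimators=[
                ("linear", LinearRegression()),
                ("tree", DecisionTreeRegressor(random_state=seed)),
                ("forest", RandomForestRegressor(random_state=seed, n_estimators=n_estimators)),
            ]
        )
    raise ValueError(f"unknown model family {name!r}")


def default_families(seed: int = 0, n_estimators: int = 100) -> dict[str, object]:
    """The six candidate regressor families, in stable comparison order."""
    names = ("linear", "svm", "decision_tree", "voting", "random_forest", "extra_trees")
    return {name: make_family(name, seed=seed, n_estimators=n_estimators) for name in names}


def screen_features_by_correlation(
    table: TrainingTable,
    r_min: float = 0.6,
    p_max: float = 0.05,
    absolute: bool = False,
) -> ScreenReport:
    """Retain features whose Pearson r against peak RAM exceeds ``r_min``.

    Signed r is used by default (``r > r_min``); with ``absolute=True`` the
    criterion becomes ``|r| > r_min``.  The two-sided P-value must also fall
    below ``p_max``.  Constant features are undefined under Pearson and are
    dropped with a warning.
    """
    if table.n_rows < 3:
        raise ValueError(f"need >= 3 rows to screen, got {table.n_rows}")
    y = table.target.to_numpy(dtype=float)
    rows = {}
    for name in table.feature_columns:
        x = table.frame[name].to_numpy(dtype=float)
        if np.isnan(x).any() or np.ptp(x) == 0.0:
            warnings.warn(f"feature {name!r} is constant or has missing values; dropped")
            rows[name] = (np.nan, np.nan, False)
            continue
        r, p = sps.pearsonr(x, y)
        score = abs(r) if absolute else r
        rows[name] = (r, p, bool(score > r_min and p < p_max))
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["r", "p_value", "retained"]
    )
    report = ScreenReport(frame=frame, r_min=r_min, p_max=p_max, absolute=absolute)
    if not report.retained:
        raise ValueError("correlation screening dropped every feature")
    return report


def _fold_rmses(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    rmses = []
    for train_idx, test_idx in folds:
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        rmses.append(float(np.sqrt(np.mean((pred - y[test_idx]) ** 2))))
    return np.asarray(rmses)


def crossvalidate_families(
    table: TrainingTable,
    families: Mapping[str, object],
    k_folds: int = 10,
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
) -> CVReport:
    """k-fold CV of every family over one identical shuffled fold partition."""
    if not families:
        raise ValueError("no model families given")
    if k_folds > table.n_rows:
        raise ValueError(f"k_folds={k_folds} exceeds number of rows ({table.n_rows})")
    X = table.features(features).to_numpy(dtype=float)
    y = table.target.to_numpy(dtype=float)
    splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(X))
    assignment = np.empty(len(y), dtype=int)
    for fold_id, (_, test_idx) in enumerate(folds):
        assignment[test_idx] = fold_id
    rows = {}
    for name, estimator in families.items():
        rmses = _fold_rmses(estimator, X, y, folds)
        rows[name] = (float(rmses.mean()), float(rmses.std()))
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_rmse_gb", "sd_rmse_gb"]
    )
    return CVReport(frame=frame, k_folds=k_folds, seed=seed, fold_assignment=assignment)


def select_family(report: CVReport) -> str:
    """Family with lowest mean RMSE; ties by lowest SD, then input order."""
    if report.frame.empty:
        raise ValueError("empty cross-validation report")
    order = {name: i for i, name in enumerate(report.families)}
    return min(
        report.families,
        key=lambda f: (
            report.frame.loc[f, "mean_rmse_gb"],
            report.frame.loc[f, "sd_rmse_gb"],
            order[f],
        ),
    )


def grid_search(
    table: TrainingTable,
    family: str,
    grid: Mapping[str, Sequence],
    k_folds: int = 10,
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
    n_estimators: int = 100,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive CV grid search; returns (best params, per-point results).

    Duplicate grid points are evaluated once.  Best = lowest mean CV RMSE,
    ties broken by enumeration order, deterministic under ``seed``.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    keys = list(grid)
    seen: set[tuple] = set()
    points: list[dict] = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        signature = tuple(zip(keys, combo))
        if signature in seen:
            continue
        seen.add(signature)
        points.append(dict(signature))
    records = []
    best_params: Optional[dict] = None
    best_mean = np.inf
    for params in points:
        estimator = make_family(family, seed=seed, n_estimators=n_estimators, **params)
        report = crossvalidate_families(
            table, {family: estimator}, k_folds=k_folds, seed=seed, features=features
        )
        mean_rmse = float(report.frame.loc[family, "mean_rmse_gb"])
        records.append({**params, "mean_rmse_gb": mean_rmse})
        if mean_rmse < best_mean:
            best_mean = mean_rmse
            best_params = params
    assert best_params is not None
    return best_params, pd.DataFrame.from_records(records)


def prune_features_by_importance(
    table: TrainingTable,
    family: str,
    params: Optional[Mapping] = None,
    keep: Union[tuple[str, object], Sequence[str]] = ("top", 2),
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
) -> list[str]:
    """Reduce the feature set using impurity-based importances.

    ``keep`` is either ``("top", m)``, ``("cumulative", fraction)``, or an
    explicit list of feature names (override — no fit performed).
    """
    if not (isinstance(keep, tuple) and len(keep) == 2 and keep[0] in ("top", "cumulative")):
        override = list(keep)
        unknown = [c for c in override if c not in table.frame.columns]
        if unknown:
            raise KeyError(f"override names not in table: {unknown}")
        return override
    estimator = make_family(family, seed=seed, **dict(params or {}))
    X = table.features(features)
    estimator.fit(X.to_numpy(dtype=float), table.target.to_numpy(dtype=float))
    if not hasattr(estimator, "feature_importances_"):
        raise TypeError(
            f"family {family!r} exposes no feature importances; "
            "pass an explicit override list instead"
        )
    importances = pd.Series(estimator.feature_importances_, index=X.columns)
    ranked = importances.sort_values(ascending=False, kind="stable")
    rule, value = keep
    if rule == "top":
        return ranked.index[: int(value)].tolist()
    cumulative = ranked.cumsum() / ranked.sum()
    n_keep = int(np.searchsorted(cumulative.to_numpy(), float(value)) + 1)
    return ranked.index[:n_keep].tolist()


def calibrate_bias(
    predictions: np.ndarray,
    observed: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    statistic: str = "q95",
    seed: int = 0,
    holdout_ids: Optional[Sequence] = None,
    training_ids: Optional[Sequence] = None,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap a confidence interval of the holdout prediction error.

    Returns ``(bias_gb, (lower, upper))`` where ``bias_gb = max(0, upper)``.
    The bootstrapped statistic of the absolute errors is the 95th percentile
    (``statistic="q95"``, the default, so that adding the bias covers the
    bulk of under-predictions) or the mean (``statistic="mean"``).
    Resampling scheme: ``rng = np.random.default_rng(seed)`` and, for each of
    ``n_boot`` replicates in order, indices ``rng.integers(0, n, size=n)``.
    """
    predictions = np.asarray(predictions, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predictions.shape != observed.shape:
        raise ValueError("predictions and observed must have the same shape")
    n = len(observed)
    if n < 10:
        raise ValueError(f"need >= 10 holdout rows to calibrate, got {n}")
    if holdout_ids is not None and training_ids is not None:
        overlap = set(holdout_ids) & set(training_ids)
        if overlap:
            raise ValueError(f"holdout overlaps training ids: {sorted(overlap)[:5]}")
    errors = np.abs(predictions - observed)
    if statistic == "mean":
        stat = lambda a: float(np.mean(a))  # noqa: E731
    elif statistic == "q95":
        stat = lambda a: float(np.quantile(a, 0.95))  # noqa: E731
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    replicates = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        replicates[b] = stat(errors[idx])
    alpha = (1.0 - level) / 2.0
    lower = float(np.quantile(replicates, alpha))
    upper = float(np.quantile(replicates, 1.0 - alpha))
    return max(0.0, upper), (lower, upper)


@dataclass
class ModelBundle:
    """A trained peak-RAM regressor plus everything needed to deploy it."""

    family: str
    params: dict
    features: list[str]
    bias_gb: float
    mode: str
    metadata: dict
    estimator: object = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.bias_gb < 0:
            raise ValueError("bias_gb must be >= 0")

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Point predictions (GB) for a frame containing the bundle features."""
        missing = [c for c in self.features if c not in features.columns]
        if missing:
            raise KeyError(f"feature table lacks bundle feature(s): {missing}")
        X = features[self.features].to_numpy(dtype=float)
        return np.asarray(self.estimator.predict(X), dtype=float)

    def predict_required(self, features: pd.DataFrame) -> np.ndarray:
        """Biased requirement: ``max(0, prediction) + bias_gb`` per dataset."""
        return np.maximum(0.0, self.predict(features)) + self.bias_gb


def fit_final_model(
    table: TrainingTable,
    family: str,
    params: Optional[Mapping] = None,
    features: Optional[Sequence[str]] = None,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    n_boot: int = 1000,
    bias_statistic: str = "q95",
) -> ModelBundle:
    """Train on a (1 - holdout) split, calibrate the bias on the holdout.

    The holdout is never seen by the regressor; its absolute prediction
    errors feed :func:`calibrate_bias`.
    """
    feats = list(features) if features is not None else table.feature_columns
    unknown = [c for c in feats if c not in table.frame.columns]
    if unknown:
        raise KeyError(f"unknown feature name(s): {unknown}")
    n = table.n_rows
    n_holdout = max(1, int(round(holdout_fraction * n)))
    if n - n_holdout < 2:
        raise ValueError("not enough rows left for training after holdout split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    holdout_idx, train_idx = order[:n_holdout], order[n_holdout:]

    X = table.features(feats).to_numpy(dtype=float)
    y = table.target.to_numpy(dtype=float)
    estimator = make_family(family, seed=seed, **dict(params or {}))
    estimator.fit(X[train_idx], y[train_idx])

    holdout_pred = np.asarray(estimator.predict(X[holdout_idx]), dtype=float)
    bias, interval = calibrate_bias(
        holdout_pred,
        y[holdout_idx],
        n_boot=n_boot,
        statistic=bias_statistic,
        seed=seed,
        holdout_ids=table.frame.index[holdout_idx],
        training_ids=table.frame.index[train_idx],
    )
    residuals = holdout_pred - y[holdout_idx]
    metadata = {
        "seed": seed,
        "n_train": int(len(train_idx)),
        "n_holdout": int(n_holdout),
        "holdout_mae_gb": float(np.mean(np.abs(residuals))),
        "holdout_rmse_gb": float(np.sqrt(np.mean(residuals**2))),
        "bias_interval_gb": [interval[0], interval[1]],
        "bias_statistic": bias_statistic,
        "holdout_ids": table.frame.index[holdout_idx].tolist(),
    }
    return ModelBundle(
        family=family,
        params=dict(params or {}),
        features=feats,
        bias_gb=bias,
        mode=table.mode,
        metadata=metadata,
        estimator=estimator,
    )


def save_bundle(bundle: ModelBundle, path) -> None:
    """Persist a bundle as a zip archive: JSON metadata + joblib payload."""
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "family": bundle.family,
        "params": bundle.params,
        "features": bundle.features,
        "bias_gb": bundle.bias_gb,
        "mode": bundle.mode,
        "metadata": bundle.metadata,
    }
    payload = _io.BytesIO()
    joblib.dump(bundle.estimator, payload)
    with zipfile.ZipFile(path, "w") as archive:
        archive.writestr("meta.json", json.dumps(meta, indent=2))
        archive.writestr("estimator.joblib", payload.getvalue())


def load_bundle(path) -> ModelBundle:
    """Load a bundle written by :func:`save_bundle`; errors on bad format."""
    try:
        with zipfile.ZipFile(path) as archive:
            meta = json.loads(archive.read("meta.json"))
            estimator = joblib.load(_io.BytesIO(archive.read("estimator.joblib")))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise BundleFormatError(f"cannot read model bundle {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleFormatError(
            f"bundle format version {version!r} unsupported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    return ModelBundle(
        family=meta["family"],
        params=meta["params"],
        features=meta["features"],
        bias_gb=meta["bias_gb"],
        mode=meta["mode"],
        metadata=meta["metadata"],
        estimator=estimator,
    )
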