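"""QSAR activity classification and potency regression with an applicability domain.

The screening models predict, per candidate structure, whether it is an AhR
agonist (binary classifier) and how potent it is (EC10 regressor, trained on
log10 EC10 in micromolar). The descriptor space is curated the way the
screening workflow prescribes: correlated descriptors are collapsed to one
representative per group (|r| > 0.95), and each descriptor is min-max
normalized to [0, 1] on the training set — the training bounding box *is*
the applicability domain, and predictions outside it are flagged rather
than withheld.

Estimators follow the scikit-learn protocol (``fit``/``predict``/
``get_params``; fitted attributes end in an underscore) and compose with
sklearn pipelines and model selection. The gradient-boosting engine is
XGBoost behind a thin interface.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .bioassay import DoseResponseSeries, fit_potency
from .errors import FitDomainError, SchemaError

__all__ = [
    "ActivityLabel",
    "EvalMetrics",
    "CorrelationFilter",
    "MinMaxDomain",
    "ActivityClassifier",
    "PotencyRegressor",
    "curate_activity",
    "reduce_correlated",
    "fit_bounds",
    "apply_bounds",
    "confusion_metrics",
    "auc_curves",
    "save_model",
    "load_model",
]


@dataclass
class ActivityLabel:
    """Curated activity call for one molecule; EC10 (uM) only for actives."""

    molecule_id: str
    active: bool
    ec10: float | None = None
    source: str = "in_house"

    def __post_init__(self):
        if self.ec10 is not None and not self.active:
            raise ValueError("EC10 present implies active")


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class EvalMetrics:
    """Confusion-matrix metrics; percentages rounded half-up to 1 decimal."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float | None
    recall: float | None
    accuracy_frac: float
    precision_frac: float | None
    recall_frac: float | None
    auc_roc: float | None = None
    auc_prc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> EvalMetrics:
    """Accuracy, precision and recall from raw confusion counts.

    Reported percentages are rounded half-up to one decimal; the raw
    fractions are kept alongside. Precision is missing (not 0) when no
    positive call was made.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("counts must be non-negative integers")
    n = sum(counts)
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / n
    prec = tp / (tp + fp) if tp + fp > 0 else None
    rec = tp / (tp + fn) if tp + fn > 0 else None
    return EvalMetrics(
        tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
        accuracy=_round1(100 * acc),
        precision=None if prec is None else _round1(100 * prec),
        recall=None if rec is None else _round1(100 * rec),
        accuracy_frac=acc, precision_frac=prec, recall_frac=rec,
    )


def auc_curves(y_true, scores) -> tuple[float, float]:
    """ROC AUC (trapezoidal) and PR AUC (step interpolation), both in %."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined for a single-class truth vector")
    return 100.0 * roc_auc_score(y_true, scores), 100.0 * average_precision_score(y_true, scores)


# ---------------------------------------------------------------------------
# activity curation
# ---------------------------------------------------------------------------


def curate_activity(
    crc_records: Sequence[tuple[str, DoseResponseSeries]],
    efficacy_min: float = 10.0,
    fit_min: float = 0.8,
    source: str = "in_house",
) -> tuple[list[ActivityLabel], list[tuple[str, str]]]:
    """Re-call activity from raw concentration-response screening records.

    A molecule is active iff its maximum efficacy exceeds ``efficacy_min``
    % of the reference compound and the low-effect linear fit is good
    (R^2 >= ``fit_min``); EC10 values for actives come from the same fit.
    Returns ``(labels, exclusions)`` where exclusions carry a reason.
    """
    labels, excluded = [], []
    for mol_id, series in crc_records:
        if len(series.concentrations) < 4:
            excluded.append((mol_id, "fewer than 4 concentration levels"))
            continue
        max_eff = float(np.max(series.effect_pct))
        if max_eff <= efficacy_min:
            labels.append(ActivityLabel(mol_id, False, source=source))
            continue
        try:
            summary = fit_potency(series)
        except FitDomainError:
            excluded.append((mol_id, "no points in the linear fit range"))
            continue
        good = (
            not summary.inactive
            and summary.fit_diagnostics is not None
            and summary.fit_diagnostics >= fit_min
        )
        if good:
            labels.append(ActivityLabel(mol_id, True, ec10=summary.ec10, source=source))
        else:
            labels.append(ActivityLabel(mol_id, False, source=source))
    return labels, excluded


# ---------------------------------------------------------------------------
# descriptor-space curation
# ---------------------------------------------------------------------------


class CorrelationFilter(TransformerMixin, BaseEstimator):
    """Drop all but one descriptor from each highly correlated group.

    Groups are the connected components of the graph linking columns with
    |Pearson r| > ``r_max``; the representative is the column with the
    fewest missing values (ties: lowest column index), making the choice
    deterministic and independent of row order. Constant columns have no
    defined correlation and are dropped with a warning.
    """

    def __init__(self, r_max: float = 0.95):
        self.r_max = r_max

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 descriptor columns")
        nunique = X.nunique(dropna=True)
        self.dropped_constant_ = [c for c in X.columns if nunique[c] <= 1]
        if self.dropped_constant_:
            warnings.warn(
                f"dropping {len(self.dropped_constant_)} constant descriptor(s)"
            )
        work = X.drop(columns=self.dropped_constant_)
        cols = list(work.columns)
        corr = work.corr().abs().to_numpy()
        n = len(cols)
        mask = np.triu(np.nan_to_num(corr) > self.r_max, k=1)
        rows, cs = np.nonzero(mask)
        adj = coo_matrix((np.ones(len(rows)), (rows, cs)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        keep = []
        for comp in np.unique(labels):
            members = [i for i in range(n) if labels[i] == comp]
            best = min(members, key=lambda i: (work[cols[i]].isna().sum(), i))
            keep.append(best)
        self.selected_columns_ = [cols[i] for i in sorted(keep)]
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = pd.DataFrame(X)
        missing = set(self.selected_columns_) - set(X.columns)
        if missing:
            raise SchemaError(f"missing descriptor columns {sorted(missing)}")
        return X[self.selected_columns_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self)
        return np.asarray(self.selected_columns_, dtype=object)


def reduce_correlated(table: pd.DataFrame, r_max: float = 0.95) -> pd.DataFrame:
    """Functional wrapper around :class:`CorrelationFilter` (fit+transform)."""
    return CorrelationFilter(r_max=r_max).fit_transform(table)


class MinMaxDomain(TransformerMixin, BaseEstimator):
    """Min-max normalization whose training box is the applicability domain.

    Transform maps every descriptor to (x - min) / (max - min) of the
    training set; training rows therefore land in [0, 1] and a prediction
    row is *in domain* iff every normalized value stays there. Constant
    descriptors normalize to 0 by convention.
    """

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        self.data_min_ = X.min(axis=0, skipna=True).to_numpy(dtype=float)
        self.data_max_ = X.max(axis=0, skipna=True).to_numpy(dtype=float)
        self.constant_ = self.data_max_ <= self.data_min_
        return self

    def _check_schema(self, X: pd.DataFrame):
        if list(X.columns) != list(self.feature_names_in_):
            unseen = set(X.columns) - set(self.feature_names_in_)
            if unseen:
                raise SchemaError(f"unseen descriptor name(s) {sorted(unseen)}")
            raise SchemaError("descriptor columns do not match the fitted schema")

    def transform(self, X):
        check_is_fitted(self)
        X = pd.DataFrame(X)
        self._check_schema(X)
        span = np.where(self.constant_, 1.0, self.data_max_ - self.data_min_)
        out = (X.to_numpy(dtype=float) - self.data_min_) / span
        out[:, self.constant_] = 0.0
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    def in_domain(self, X) -> np.ndarray:
        """Row-wise flag: all normalized values within [0, 1] (NaNs excluded)."""
        Z = self.transform(X).to_numpy()
        eps = 1e-12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ok = np.nanmin(Z, axis=1) >= -eps
            ok &= np.nanmax(Z, axis=1) <= 1 + eps
        return ok

    def to_dict(self) -> dict:
        check_is_fitted(self)
        return {
            "feature_names": list(self.feature_names_in_),
            "min": self.data_min_.tolist(),
            "max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxDomain":
        obj = cls()
        obj.feature_names_in_ = np.asarray(d["feature_names"], dtype=object)
        obj.n_features_in_ = len(d["feature_names"])
        obj.data_min_ = np.asarray(d["min"], dtype=float)
        obj.data_max_ = np.asarray(d["max"], dtype=float)
        obj.constant_ = obj.data_max_ <= obj.data_min_
        return obj


def fit_bounds(table: pd.DataFrame) -> MinMaxDomain:
    return MinMaxDomain().fit(table)


def apply_bounds(table: pd.DataFrame, bounds: MinMaxDomain):
    """Normalize a descriptor table and flag rows outside the domain."""
    return bounds.transform(table), bounds.in_domain(table)


# ---------------------------------------------------------------------------
# gradient-boosted models
# ---------------------------------------------------------------------------


def _as_frame(X) -> pd.DataFrame:
    X = pd.DataFrame(X)
    if X.shape[0] == 0:
        raise ValueError("empty descriptor table")
    return X


class _BoostedBase(BaseEstimator):
    """Shared plumbing: median imputation, min-max domain, XGBoost engine."""

    def __init__(self, n_estimators=500, max_depth=6, learning_rate=0.05, random_state=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _prepare_fit(self, X):
        X = _as_frame(X)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        self.medians_ = X.median(axis=0, skipna=True)
        Xi = X.fillna(self.medians_)
        self.bounds_ = MinMaxDomain().fit(Xi)
        return self.bounds_.transform(Xi)

    def _prepare_predict(self, X):
        check_is_fitted(self, "bounds_")
        X = _as_frame(X)
        in_dom = self.bounds_.in_domain(X.fillna(self.medians_))
        Z = self.bounds_.transform(X.fillna(self.medians_))
        return Z, in_dom

    def in_domain(self, X) -> np.ndarray:
        check_is_fitted(self, "bounds_")
        return self.bounds_.in_domain(_as_frame(X).fillna(self.medians_))


class ActivityClassifier(ClassifierMixin, _BoostedBase):
    """Binary agonist-vs-inactive classifier over the curated descriptor space.

    A gradient-boosted tree ensemble (500 trees, depth 6, learning rate
    0.05 by default) with class weighting inversely proportional to class
    frequency. Deterministic given (data, hyperparameters, random_state).
    Out-of-domain rows are still predicted but flagged by
    :meth:`predict_frame` / :meth:`in_domain`.
    """

    def fit(self, X, y):
        from xgboost import XGBClassifier

        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        Z = self._prepare_fit(X)
        n_pos = int((y == 1).sum())
        self.model_ = XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
            scale_pos_weight=(len(y) - n_pos) / n_pos,
            n_jobs=1,
            eval_metric="logloss",
        )
        self.model_.fit(Z.to_numpy(), y)
        self.classes_ = classes
        return self

    def predict_proba(self, X) -> np.ndarray:
        Z, _ = self._prepare_predict(X)
        return self.model_.predict_proba(Z.to_numpy())

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1] >= 0.5

    def predict_frame(self, X) -> pd.DataFrame:
        """Probabilities, labels and applicability-domain flags per row."""
        Z, in_dom = self._prepare_predict(X)
        proba = self.model_.predict_proba(Z.to_numpy())[:, 1]
        return pd.DataFrame(
            {"probability": proba, "active": proba >= 0.5, "in_domain": in_dom},
            index=_as_frame(X).index,
        )


class PotencyRegressor(RegressorMixin, _BoostedBase):
    """EC10 regressor trained on log10(EC10/uM) of active molecules.

    ``fit`` takes EC10 in micromolar (strictly positive) and models its
    log10; ``predict`` returns micromolar values back-transformed from the
    log scale. Same engine, domain handling and determinism contract as
    the classifier.
    """

    def fit(self, X, ec10_um):
        from xgboost import XGBRegressor

        y = np.asarray(ec10_um, dtype=float)
        if np.any(~np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("EC10 targets must be finite and positive (uM)")
        Z = self._prepare_fit(X)
        self.model_ = XGBRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.model_.fit(Z.to_numpy(), np.log10(y))
        return self

    def predict_log10(self, X) -> np.ndarray:
        Z, _ = self._prepare_predict(X)
        return self.model_.predict(Z.to_numpy())

    def predict(self, X) -> np.ndarray:
        return 10.0 ** self.predict_log10(X)

    def predict_frame(self, X) -> pd.DataFrame:
        Z, in_dom = self._prepare_predict(X)
        log_pred = self.model_.predict(Z.to_numpy())
        return pd.DataFrame(
            {"ec10_um": 10.0**log_pred, "log10_ec10": log_pred, "in_domain": in_dom},
            index=_as_frame(X).index,
        )


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def _schema_hash(names) -> str:
    return hashlib.sha256("\n".join(map(str, names)).encode()).hexdigest()[:16]


def save_model(model: _BoostedBase, directory) -> None:
    """Persist a fitted model: engine blob + bounds JSON + seed + schema hash."""
    check_is_fitted(model, "model_")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    model.model_.get_booster().save_model(d / "engine.json")
    (d / "bounds.json").write_text(json.dumps(model.bounds_.to_dict()))
    meta = {
        "kind": "classifier" if isinstance(model, ActivityClassifier) else "regressor",
        "params": model.get_params(),
        "seed": model.random_state,
        "schema_hash": _schema_hash(model.feature_names_in_),
        "medians": model.medians_.to_dict(),
    }
    (d / "meta.json").write_text(json.dumps(meta))


def load_model(directory) -> "ActivityClassifier | PotencyRegressor":
    import xgboost as xgb

    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    cls = ActivityClassifier if meta["kind"] == "classifier" else PotencyRegressor
    model = cls(**meta["params"])
    model.bounds_ = MinMaxDomain.from_dict(json.loads((d / "bounds.json").read_text()))
    model.feature_names_in_ = model.bounds_.feature_names_in_
    model.n_features_in_ = model.bounds_.n_features_in_
    model.medians_ = pd.Series(meta["medians"])
    booster = xgb.Booster()
    booster.load_model(d / "engine.json")
    engine = xgb.XGBClassifier() if meta["kind"] == "classifier" else xgb.XGBRegressor()
    engine._Booster = booster
    if meta["kind"] == "classifier":
        engine.n_classes_ = 2
        model.classes_ = np.array([0, 1])
    model.model_ = engine
    return model
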