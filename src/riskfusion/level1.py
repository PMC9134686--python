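"""Single-database (Level 1) LASSO logistic models and shareable model cards.

Each database/outcome pair gets its own L1-penalised logistic regression:
80% of the database develops the model (with 3-fold stratified
cross-validation selecting the penalty that maximises discrimination) and
the held-out 20% provides the internal validation.  The fitted model plus
the aggregate quantities the ensemble schemes need — internal AUROC,
development-population feature means, mean age and outcome rate — are
packaged into a JSON-serialisable *model card* so ensembles can be built
without ever moving patient-level data between databases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import metrics
from .exceptions import AlignmentError, NoEventsError, StratificationError
from .simdata import LabelledDataset

__all__ = [
    "DEFAULT_PENALTY_GRID",
    "Level1Model",
    "ModelCard",
    "InternalValidation",
    "split_train_test",
    "fit_lasso_logistic",
    "predict_risk",
    "internal_validation",
    "make_model_card",
    "card_to_dict",
    "card_from_dict",
    "save_card",
    "load_card",
]

# log-spaced penalty strengths on the inverse-prior-variance scale; the grid
# is wide enough that the weak end is effectively unpenalised and the strong
# end shrinks every feature coefficient to zero (intercept-only model).
DEFAULT_PENALTY_GRID = tuple(np.logspace(-4, 2, 25))


@dataclass(frozen=True)
class Level1Model:
    db_id: str
    outcome_id: str
    coefficients: np.ndarray
    intercept: float
    penalty: float
    feature_names: tuple

    def __post_init__(self):
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficient length must equal feature_names length")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")

    @property
    def included_features(self) -> tuple:
        """Features retained by the LASSO (nonzero coefficient)."""
        coef = np.asarray(self.coefficients)
        return tuple(n for n, c in zip(self.feature_names, coef) if c != 0.0)


@dataclass(frozen=True)
class InternalValidation:
    """Test-split performance of a Level-1 model in its own database."""

    auroc: float
    calibration_in_the_large: float
    calibration_gradient: float  # NaN when undefined on the test split
    predictions: np.ndarray
    labels: np.ndarray


@dataclass(frozen=True)
class ModelCard:
    """The shareable artifact of one Level-1 model.

    Carries everything any ensemble scheme needs: the model itself, its
    internal AUROC, and development-population summaries (means of the
    included features, mean age, outcome rate).
    """

    model: Level1Model
    internal_auroc: float
    internal_citl: float
    internal_gradient: float
    dev_feature_means: dict
    dev_mean_age: float
    dev_outcome_rate: float
    train_n: int
    test_n: int
    degenerate: bool = field(default=False)

    def __post_init__(self):
        if not 0.0 <= self.internal_auroc <= 1.0:
            raise ValueError("internal_auroc must lie in [0, 1]")
        for v in self.dev_feature_means.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("dev_feature_means entries must lie in [0, 1]")

    @property
    def db_id(self) -> str:
        return self.model.db_id

    @property
    def outcome_id(self) -> str:
        return self.model.outcome_id


def _subset(ds: LabelledDataset, idx: np.ndarray) -> LabelledDataset:
    return LabelledDataset(
        db_id=ds.db_id,
        features=ds.features.iloc[idx].reset_index(drop=True),
        age_years=ds.age_years[idx],
        labels={k: v[idx] for k, v in ds.labels.items()},
    )


def split_train_test(
    ds: LabelledDataset, outcome_id: str, test_fraction: float = 0.2, seed: int = 0
) -> tuple[LabelledDataset, LabelledDataset]:
    """Disjoint, exhaustive 80/20-style partition stratified by outcome."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = np.asarray(ds.labels[outcome_id])
    n_events = int(y.sum())
    if n_events < 2 or (len(y) - n_events) < 2:
        raise StratificationError(
            f"outcome {outcome_id!r} in {ds.db_id!r} has too few events "
            f"({n_events}/{len(y)}) for a stratified split"
        )
    n_test = int(round(len(y) * test_fraction))
    if n_test < 2 or len(y) - n_test < 2:
        raise StratificationError("split leaves fewer than 2 patients on one side")
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=test_fraction, stratify=y, random_state=seed
    )
    return _subset(ds, np.sort(idx_train)), _subset(ds, np.sort(idx_test))


def _fit_at(X: np.ndarray, y: np.ndarray, penalty: float, seed: int) -> LogisticRegression:
    # per-observation scaling keeps the penalty meaning stable across n
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (penalty * len(y)),
        solver="liblinear",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def fit_lasso_logistic(
    train: LabelledDataset,
    outcome_id: str,
    penalty_grid=None,
    cv_folds: int = 3,
    seed: int = 0,
) -> Level1Model:
    """Select the LASSO penalty by cross-validated AUROC and refit.

    The penalty maximising the mean validation-fold AUROC is selected
    (ties broken toward the strongest penalty, i.e. the sparsest model) and
    the final model is refitted on the full training split at that penalty.
    The intercept is never penalised.
    """
    grid = np.asarray(penalty_grid if penalty_grid is not None else DEFAULT_PENALTY_GRID, float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("penalty_grid must be non-empty with positive strengths")

    y = np.asarray(train.labels[outcome_id])
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise NoEventsError(f"all labels identical for outcome {outcome_id!r}")
    if n_events < cv_folds or (len(y) - n_events) < cv_folds:
        raise StratificationError(
            f"need at least {cv_folds} patients of each class for {cv_folds}-fold CV"
        )

    X = train.features.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    mean_auc = np.empty(grid.size)
    for g, penalty in enumerate(grid):
        aucs = []
        for tr, va in folds:
            clf = _fit_at(X[tr], y[tr], penalty, seed)
            score = X[va] @ clf.coef_[0] + clf.intercept_[0]
            if y[va].min() == y[va].max():  # pragma: no cover - stratification prevents
                continue
            aucs.append(metrics.auroc(metrics.ScoredPredictions(score, y[va])))
        mean_auc[g] = np.mean(aucs) if aucs else np.nan
    if np.all(np.isnan(mean_auc)):
        raise NoEventsError("no penalty yielded an evaluable cross-validated fit")

    best = np.nanmax(mean_auc)
    tied = np.flatnonzero(mean_auc >= best - 1e-12)
    chosen = float(grid[tied[np.argmax(grid[tied])]])

    final = _fit_at(X, y, chosen, seed)
    return Level1Model(
        db_id=train.db_id,
        outcome_id=outcome_id,
        coefficients=final.coef_[0].copy(),
        intercept=float(final.intercept_[0]),
        penalty=chosen,
        feature_names=tuple(train.features.columns),
    )


def predict_risk(model: Level1Model, features: pd.DataFrame) -> np.ndarray:
    """expit(intercept + x.beta), aligning columns by name.

    Columns absent from ``features`` contribute zero — an unobserved stratum
    (e.g. ages above a database's truncation point) simply carries no signal.
    """
    present = [n for n in model.feature_names if n in features.columns]
    if not present:
        raise AlignmentError("no overlap between model features and supplied columns")
    X = np.zeros((len(features), len(model.feature_names)))
    name_to_idx = {n: i for i, n in enumerate(model.feature_names)}
    cols = features[present].to_numpy(dtype=float)
    for j, n in enumerate(present):
        X[:, name_to_idx[n]] = cols[:, j]
    return expit(model.intercept + X @ np.asarray(model.coefficients))


def internal_validation(
    model: Level1Model, test: LabelledDataset, n_bins: int = 100
) -> InternalValidation:
    """Discrimination and calibration of the model on its 20% test split."""
    preds = predict_risk(model, test.features)
    y = np.asarray(test.labels[model.outcome_id])
    sp = metrics.ScoredPredictions(preds, y)
    try:
        gradient = metrics.calibration_gradient(sp, n_bins=n_bins)
    except Exception:
        gradient = float("nan")
    return InternalValidation(
        auroc=metrics.auroc(sp),
        calibration_in_the_large=metrics.calibration_in_the_large(sp),
        calibration_gradient=gradient,
        predictions=preds,
        labels=y,
    )


def make_model_card(
    model: Level1Model,
    train: LabelledDataset,
    test: LabelledDataset,
    validation: InternalValidation | None = None,
) -> ModelCard:
    """Assemble the portable card: model + internal metrics + dev summaries."""
    if validation is None:
        validation = internal_validation(model, test)
    included = model.included_features
    degenerate = len(included) == 0
    if degenerate:
        dev_means = {}
    else:
        means = train.features[list(included)].to_numpy(dtype=float).mean(axis=0)
        dev_means = {n: float(v) for n, v in zip(included, means)}
    y_train = np.asarray(train.labels[model.outcome_id])
    return ModelCard(
        model=model,
        internal_auroc=validation.auroc,
        internal_citl=validation.calibration_in_the_large,
        internal_gradient=validation.calibration_gradient,
        dev_feature_means=dev_means,
        dev_mean_age=float(np.mean(train.age_years)),
        dev_outcome_rate=float(y_train.mean()),
        train_n=train.n,
        test_n=test.n,
        degenerate=degenerate,
    )


_CARD_SCHEMA_VERSION = 1


def card_to_dict(card: ModelCard) -> dict:
    m = card.model
    coef = np.asarray(m.coefficients)
    sparse = {n: float(c) for n, c in zip(m.feature_names, coef) if c != 0.0}
    return {
        "schema_version": _CARD_SCHEMA_VERSION,
        "db_id": m.db_id,
        "outcome_id": m.outcome_id,
        "feature_names": list(m.feature_names),
        "coefficients": sparse,
        "intercept": m.intercept,
        "penalty": m.penalty,
        "internal_auroc": card.internal_auroc,
        "internal_citl": card.internal_citl,
        "internal_gradient": card.internal_gradient,
        "dev_feature_means": dict(card.dev_feature_means),
        "dev_mean_age": card.dev_mean_age,
        "dev_outcome_rate": card.dev_outcome_rate,
        "train_n": card.train_n,
        "test_n": card.test_n,
        "degenerate": card.degenerate,
    }


def card_from_dict(d: dict) -> ModelCard:
    names = tuple(d["feature_names"])
    coef = np.array([d["coefficients"].get(n, 0.0) for n in names])
    model = Level1Model(
        db_id=d["db_id"],
        outcome_id=d["outcome_id"],
        coefficients=coef,
        intercept=float(d["intercept"]),
        penalty=float(d["penalty"]),
        feature_names=names,
    )
    return ModelCard(
        model=model,
        internal_auroc=float(d["internal_auroc"]),
        internal_citl=float(d["internal_citl"]),
        internal_gradient=float(d["internal_gradient"]),
        dev_feature_means={k: float(v) for k, v in d["dev_feature_means"].items()},
        dev_mean_age=float(d["dev_mean_age"]),
        dev_outcome_rate=float(d["dev_outcome_rate"]),
        train_n=int(d["train_n"]),
        test_n=int(d["test_n"]),
        degenerate=bool(d["degenerate"]),
    )


def save_card(card: ModelCard, path) -> None:
    with open(path, "w") as fh:
        json.dump(card_to_dict(card), fh, indent=1, sort_keys=True)


def load_card(path) -> ModelCard:
    with open(path) as fh:
        return card_from_dict(json.load(fh))
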