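"""Level-2 ensembles combining single-database model cards.

Seven schemes combine N Level-1 models f_i that predict the same outcome:

* fusion, fixed per-model weights w_i applied to each patient's risks:
  ``mean``   w_i = 1/N;
  ``auc1``   w_i = |AUROC_i - 0.5| / sum_k |AUROC_k - 0.5| (normalised);
  ``auc2``   w_i = (AUROC_i - 0.5) / 0.5 (NOT normalised; combined risks
  can leave [0, 1] and are returned unclamped — the miscalibration this
  induces is part of what the evaluation measures);
  ``sim``    w_i proportional to the cosine similarity between the
  application population's mean values of model i's included features and
  the same means in model i's development population;
  ``age``    w_i proportional to 1 / (1 + |mu_age - age_i|), mu_age the
  application population's mean age, age_i the development mean age;
* ``ageME`` mixture of experts: each patient is scored by the one model
  whose development mean age is closest to the patient's own age;
* stacking: an unpenalised logistic regression on the member risks, fitted
  on a labelled (sub)sample of the application database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgWarning
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .exceptions import AlignmentError, DegenerateWeightsError, NoEventsError
from .level1 import ModelCard, predict_risk
from .simdata import LabelledDataset, population_feature_means

__all__ = [
    "FUSION_SCHEMES",
    "WeightVector",
    "ApplicationContext",
    "StackingModel",
    "application_context",
    "compute_fusion_weights",
    "apply_fusion",
    "member_predictions",
    "age_mixture_gate",
    "apply_age_mixture",
    "fit_stacking",
    "predict_stacking",
]

FUSION_SCHEMES = ("mean", "auc1", "auc2", "sim", "age")
_NORMALIZED = ("mean", "auc1", "sim", "age")


@dataclass(frozen=True)
class WeightVector:
    """Per-model fusion weights, keyed by development database."""

    weights: dict  # db_id -> weight
    scheme: str

    def __post_init__(self):
        if self.scheme not in FUSION_SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme in _NORMALIZED:
            total = sum(self.weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.scheme} weights must sum to 1 (got {total!r})")


@dataclass(frozen=True)
class ApplicationContext:
    """Population summaries of the dataset an ensemble is applied to."""

    feature_means: dict  # column name -> mean in the application population
    mean_age: float
    patient_ages: np.ndarray | None = None


def application_context(ds: LabelledDataset) -> ApplicationContext:
    """Summarise a dataset for similarity/age weighting and age gating."""
    means = population_feature_means(ds, list(ds.features.columns))
    return ApplicationContext(
        feature_means={n: float(v) for n, v in zip(ds.features.columns, means)},
        mean_age=float(np.mean(ds.age_years)),
        patient_ages=np.asarray(ds.age_years, dtype=float),
    )


def _check_cards(cards: list[ModelCard]) -> None:
    if len(cards) < 2:
        raise ValueError("an ensemble needs at least 2 member cards")
    outcomes = {c.outcome_id for c in cards}
    if len(outcomes) != 1:
        raise ValueError(f"member cards predict different outcomes: {sorted(outcomes)}")
    ids = [c.db_id for c in cards]
    if len(set(ids)) != len(ids):
        raise ValueError("member cards must come from distinct databases")


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def compute_fusion_weights(
    scheme: str, cards: list[ModelCard], ctx: ApplicationContext | None = None
) -> WeightVector:
    """Fixed (patient-independent) fusion weights under the named scheme.

    ``sim`` restricts the application/development mean vectors to each
    model's own included features; a degenerate card (no included features)
    gets cosine 0 and is thereby excluded.  When every numerator of a
    normalised scheme vanishes a :class:`DegenerateWeightsError` is raised
    carrying uniform mean weights as the documented fallback.
    """
    _check_cards(cards)
    if scheme not in FUSION_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme in ("sim", "age") and ctx is None:
        raise ValueError(f"scheme {scheme!r} requires an ApplicationContext")

    n = len(cards)
    ids = [c.db_id for c in cards]
    if scheme == "mean":
        return WeightVector({i: 1.0 / n for i in ids}, "mean")
    if scheme == "auc2":
        return WeightVector(
            {c.db_id: (c.internal_auroc - 0.5) / 0.5 for c in cards}, "auc2"
        )

    if scheme == "auc1":
        raw = np.array([abs(c.internal_auroc - 0.5) for c in cards])
    elif scheme == "age":
        raw = np.array([1.0 / (1.0 + abs(ctx.mean_age - c.dev_mean_age)) for c in cards])
    else:  # sim
        raw = np.empty(n)
        for i, c in enumerate(cards):
            feats = list(c.dev_feature_means)
            if not feats:
                warnings.warn(
                    f"card {c.db_id!r} has no included features; excluded from sim weighting",
                    stacklevel=2,
                )
                raw[i] = 0.0
                continue
            d_app = np.array([ctx.feature_means.get(f, 0.0) for f in feats])
            d_dev = np.array([c.dev_feature_means[f] for f in feats])
            raw[i] = _cosine(d_app, d_dev)

    total = raw.sum()
    if total <= 0.0:
        raise DegenerateWeightsError(
            f"all {scheme} weight numerators are zero",
            fallback=WeightVector({i: 1.0 / n for i in ids}, "mean"),
        )
    return WeightVector(dict(zip(ids, raw / total)), scheme)


def member_predictions(cards: list[ModelCard], features) -> dict:
    """Each member's risk vector on a common feature table, keyed by db_id."""
    return {c.db_id: predict_risk(c.model, features) for c in cards}


def _aligned_matrix(keys, preds: dict) -> np.ndarray:
    if set(keys) != set(preds):
        raise AlignmentError(
            f"member keys {sorted(preds)} do not match expected {sorted(keys)}"
        )
    cols = [np.asarray(preds[k], dtype=float) for k in keys]
    lengths = {len(c) for c in cols}
    if len(lengths) != 1:
        raise AlignmentError("member prediction vectors have differing lengths")
    return np.column_stack(cols)


def apply_fusion(w: WeightVector, preds: dict) -> np.ndarray:
    """Per-patient weighted sum of member risks; auc2 output is unclamped."""
    keys = list(w.weights)
    mat = _aligned_matrix(keys, preds)
    return mat @ np.array([w.weights[k] for k in keys])


def age_mixture_gate(cards: list[ModelCard], patient_ages) -> tuple[np.ndarray, list]:
    """One-hot per-patient gating to the nearest-development-mean-age model.

    Returns the (n_patients, n_models) 0/1 gate matrix and the member db_id
    order of its columns.  Ties break toward the lexicographically lowest
    db_id.
    """
    _check_cards(cards)
    if patient_ages is None:
        raise ValueError("patient ages are required for age gating")
    ages = np.asarray(patient_ages, dtype=float)
    ordered = sorted(cards, key=lambda c: c.db_id)
    dev_ages = np.array([c.dev_mean_age for c in ordered])
    dist = np.abs(dev_ages[None, :] - ages[:, None])
    winner = np.argmin(dist, axis=1)  # argmin takes the first (lowest db_id) on ties
    gate = np.zeros_like(dist, dtype=np.uint8)
    gate[np.arange(len(ages)), winner] = 1
    return gate, [c.db_id for c in ordered]


def apply_age_mixture(cards: list[ModelCard], preds: dict, patient_ages) -> np.ndarray:
    gate, order = age_mixture_gate(cards, patient_ages)
    mat = _aligned_matrix(order, preds)
    return (mat * gate).sum(axis=1)


@dataclass(frozen=True)
class StackingModel:
    """Level-2 logistic regression over member risk columns."""

    coefficients: dict  # db_id -> coefficient on that member's risk
    intercept: float
    n_labels_used: int
    diagnostics: dict = field(default_factory=dict)


def fit_stacking(
    cards: list[ModelCard],
    application_sample: LabelledDataset,
    n_labels: int | None = None,
    seed: int = 0,
    use_logit_inputs: bool = False,
) -> StackingModel:
    """Fit the stacking meta-model on a labelled subsample.

    Draws a simple random (unstratified) subsample of ``n_labels`` patients
    — unstratified on purpose: running out of events in a small labelled
    subsample is precisely the failure mode the rare-outcome evaluation
    probes — computes each member's risk on it, and fits an unpenalised
    logistic regression of the outcome on the member risks.  ``n_labels
    = None`` uses every patient.  ``use_logit_inputs`` switches the
    predictors to logit-risks (off by default; raw risks match the reference
    design).
    """
    _check_cards(cards)
    outcome = cards[0].outcome_id
    n = application_sample.n
    if n_labels is not None:
        if n_labels <= 0:
            raise ValueError("n_labels must be positive")
        if n_labels > n:
            raise ValueError(f"n_labels={n_labels} exceeds sample size {n}")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=n_labels, replace=False))
    else:
        idx = np.arange(n)

    y = np.asarray(application_sample.labels[outcome])[idx]
    if y.sum() == 0 or y.sum() == len(y):
        raise NoEventsError(
            f"stacking subsample of {len(y)} patients has no "
            f"{'events' if y.sum() == 0 else 'non-events'} for outcome {outcome!r}"
        )

    feats = application_sample.features.iloc[idx]
    preds = member_predictions(cards, feats)
    order = [c.db_id for c in cards]
    X = _aligned_matrix(order, preds)
    if use_logit_inputs:
        eps = 1e-12
        X = np.log(np.clip(X, eps, 1 - eps) / (1 - np.clip(X, eps, 1 - eps)))

    # exact-Newton solver at tight tolerance: the MLE score equation then
    # zeroes calibration-in-the-large on the fitting sample to ~1e-10
    clf = LogisticRegression(C=np.inf, solver="newton-cholesky", tol=1e-10, max_iter=500)
    converged = True
    with warnings.catch_warnings():
        # collinear member risks (e.g. a constant member) make the Hessian
        # singular; the solver's internal fallback handles it
        warnings.simplefilter("ignore", LinAlgWarning)
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning:
            converged = False  # near-separation: refit without the tripwire
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X, y)

    return StackingModel(
        coefficients=dict(zip(order, clf.coef_[0].astype(float))),
        intercept=float(clf.intercept_[0]),
        n_labels_used=len(idx),
        diagnostics={
            "converged": converged,
            "n_events": int(y.sum()),
            "use_logit_inputs": use_logit_inputs,
        },
    )


def predict_stacking(stack: StackingModel, preds: dict) -> np.ndarray:
    """expit(intercept + sum_i coef_i * risk_i); outputs in (0, 1)."""
    keys = list(stack.coefficients)
    X = _aligned_matrix(keys, preds)
    if stack.diagnostics.get("use_logit_inputs"):
        eps = 1e-12
        X = np.log(np.clip(X, eps, 1 - eps) / (1 - np.clip(X, eps, 1 - eps)))
    beta = np.array([stack.coefficients[k] for k in keys])
    return expit(stack.intercept + X @ beta)
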