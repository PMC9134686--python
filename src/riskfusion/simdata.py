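"""Synthetic heterogeneous healthcare-style databases.

Real multi-database prognostic studies draw patients from claims/EHR sources
that differ in age structure, case mix and outcome rates.  This module
generates databases with exactly that statistical structure from a *shared*
outcome-generating logistic model: every database uses the same feature
coefficients, while heterogeneity enters through

* database-specific age distributions (including one age-truncated source,
  emulating an employer-claims population capped at 65),
* per-feature prevalence shifts on the logit scale (case-mix shift), and
* a per-database intercept shift in the outcome model (rate shift).

A shared-coefficient world isolates the mechanisms the transportability
analysis is designed to detect, and makes the internal benchmark a meaningful
upper bound on external performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, truncnorm

from .exceptions import InvalidScenarioError

__all__ = [
    "AGE_BIN_NAMES",
    "MALE_COLUMN",
    "DatabaseProfile",
    "GroundTruth",
    "LabelledDataset",
    "age_bin_index",
    "default_scenario",
    "homogeneous_scenario",
    "simulate_database",
    "simulate_scenario",
    "population_feature_means",
]

# 5-year half-open bins [0,5), [5,10), ..., capped at [95, inf)
N_AGE_BINS = 20
AGE_BIN_NAMES = tuple(
    f"age_{5 * i:02d}_{5 * i + 4:02d}" for i in range(N_AGE_BINS - 1)
) + ("age_95_plus",)
MALE_COLUMN = "male"


def age_bin_index(age_years: np.ndarray) -> np.ndarray:
    """Map continuous ages (years) to 5-year bin indices, capped at [95, inf)."""
    return np.minimum(np.asarray(age_years, dtype=float) // 5, N_AGE_BINS - 1).astype(int)


@dataclass(frozen=True)
class DatabaseProfile:
    """Sampling recipe for one synthetic database."""

    db_id: str
    n_patients: int
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float
    male_fraction: float
    prevalence_shift: np.ndarray  # per condition/drug feature, logit scale
    intercept_shift: float  # log-odds offset of the outcome model
    sample_cap: int | None = None

    def __post_init__(self):
        if not 0.0 < self.male_fraction < 1.0:
            raise InvalidScenarioError("male_fraction must lie in (0, 1)")
        if not self.age_min < self.age_max:
            raise InvalidScenarioError("age_min must be below age_max")
        if self.age_sd <= 0:
            raise InvalidScenarioError("age_sd must be positive")
        if self.n_patients <= 0:
            raise InvalidScenarioError("n_patients must be positive")
        if self.sample_cap is not None and self.sample_cap <= 0:
            raise InvalidScenarioError("sample_cap must be positive when set")

    @property
    def effective_n(self) -> int:
        """Row count after applying the sampling cap."""
        if self.sample_cap is None:
            return self.n_patients
        return min(self.n_patients, self.sample_cap)


@dataclass(frozen=True)
class GroundTruth:
    """The shared data-generating process behind every database.

    ``feature_names`` covers the full design matrix: condition/drug
    indicators, then the 5-year age-bin indicators, then the male indicator.
    ``baseline_prevalence`` entries for the derived columns (age bins,
    gender) are nominal placeholders — those columns are generated from
    continuous age and ``male_fraction``, never sampled from the prevalence.
    """

    feature_names: tuple
    baseline_prevalence: np.ndarray
    beta: np.ndarray
    beta0: dict  # outcome_id -> global intercept (log-odds)
    outcome_ids: tuple
    n_condition_features: int = field(default=0)

    def __post_init__(self):
        m = len(self.feature_names)
        if not (len(self.baseline_prevalence) == len(self.beta) == m):
            raise InvalidScenarioError(
                "feature_names, baseline_prevalence and beta lengths must agree"
            )
        if m == 0:
            raise InvalidScenarioError("feature list must be non-empty")
        prev = np.asarray(self.baseline_prevalence)
        if np.any(prev <= 0) or np.any(prev >= 1):
            raise InvalidScenarioError("baseline_prevalence entries must lie in (0, 1)")

    @property
    def condition_features(self) -> tuple:
        return self.feature_names[: self.n_condition_features]


@dataclass
class LabelledDataset:
    """One database's binary design matrix, continuous ages and outcome labels."""

    db_id: str
    features: pd.DataFrame  # n x m, entries in {0, 1}
    age_years: np.ndarray
    labels: dict  # outcome_id -> length-n {0,1} vector

    @property
    def n(self) -> int:
        return len(self.features)

    def outcome_rate(self, outcome_id: str) -> float:
        return float(np.mean(self.labels[outcome_id]))


def _age_bin_betas(slope_per_year: float = 0.045, pivot: float = 50.0) -> np.ndarray:
    """Log-odds per age bin, linear in the bin midpoint.

    Age is a strong predictor here by design: it is what makes the
    age-truncated database's model genuinely less transportable to an
    elderly population.
    """
    midpoints = np.array([5 * i + 2.5 for i in range(N_AGE_BINS - 1)] + [97.5])
    return slope_per_year * (midpoints - pivot)


def _expected_linear_predictor(
    truth_beta: np.ndarray,
    baseline_prevalence: np.ndarray,
    n_cond: int,
    age_mean: float,
    age_sd: float,
    male_fraction: float,
) -> float:
    """Population-average x.beta under nominal marginals (used to centre beta0)."""
    cond = float(baseline_prevalence[:n_cond] @ truth_beta[:n_cond])
    edges = np.array([5.0 * i for i in range(N_AGE_BINS)] + [np.inf])
    bin_probs = norm.cdf(edges[1:], age_mean, age_sd) - norm.cdf(edges[:-1], age_mean, age_sd)
    bin_probs = bin_probs / bin_probs.sum()
    age = float(bin_probs @ truth_beta[n_cond : n_cond + N_AGE_BINS])
    male = male_fraction * float(truth_beta[-1])
    return cond + age + male


# Outcome base rates emulating the observed rare/medium/common spread
# (roughly 0.02%-10% once per-database intercept shifts are applied).
_DEFAULT_OUTCOME_RATES = {"rare": 0.001, "medium": 0.008, "common": 0.06}

# Characteristic age means of five US claims/EHR depression cohorts; the
# youngest-mean source is an employer database capped at age 65.
_FIVE_DB_AGE_MEANS = (41.0, 35.0, 75.0, 50.0, 49.0)
_TRUNCATED_INDEX = 0


def _build_truth(n_features: int, rng: np.random.Generator) -> GroundTruth:
    cond_names = tuple(f"feat_{i:03d}" for i in range(n_features))
    feature_names = cond_names + AGE_BIN_NAMES + (MALE_COLUMN,)

    cond_prev = rng.uniform(0.01, 0.35, size=n_features)
    # placeholders for derived columns (never sampled from)
    baseline_prevalence = np.concatenate(
        [cond_prev, np.full(N_AGE_BINS, 1.0 / N_AGE_BINS), [0.3]]
    )

    cond_beta = rng.normal(0.0, 0.5, size=n_features)
    cond_beta[rng.random(n_features) > 0.4] = 0.0  # sparse signal
    beta = np.concatenate([cond_beta, _age_bin_betas(), [0.3]])

    nominal_lp = _expected_linear_predictor(
        beta, baseline_prevalence, n_features, age_mean=52.0, age_sd=14.0, male_fraction=0.3
    )
    beta0 = {
        outcome: float(logit(rate) - nominal_lp)
        for outcome, rate in _DEFAULT_OUTCOME_RATES.items()
    }
    return GroundTruth(
        feature_names=feature_names,
        baseline_prevalence=baseline_prevalence,
        beta=beta,
        beta0=beta0,
        outcome_ids=tuple(_DEFAULT_OUTCOME_RATES),
        n_condition_features=n_features,
    )


def default_scenario(
    n_databases: int, n_features: int, seed: int, n_per_db: int = 20_000
) -> tuple[list[DatabaseProfile], GroundTruth]:
    """Heterogeneous study conditions: age-shifted databases, one truncated at 65.

    Age means span [35, 75]; per-database intercept shifts spread the outcome
    rates; case mix differs through logit-scale prevalence shifts.  One
    database requests more patients than its sampling cap allows, exercising
    the random-sample-cap behaviour of large claims sources.
    """
    if n_databases < 2:
        raise InvalidScenarioError(
            "need at least 2 databases (leave-one-out requires >=1 training db plus 1 held out)"
        )
    if n_features < 5:
        raise InvalidScenarioError("need at least 5 condition/drug features")

    rng = np.random.default_rng(seed)
    truth = _build_truth(n_features, rng)

    if n_databases == 5:
        age_means = np.array(_FIVE_DB_AGE_MEANS)
        truncated = _TRUNCATED_INDEX
    else:
        age_means = np.linspace(35.0, 75.0, n_databases)
        truncated = 0
    intercept_shifts = np.linspace(-0.8, 0.8, n_databases)

    profiles = []
    for i in range(n_databases):
        is_trunc = i == truncated
        profiles.append(
            DatabaseProfile(
                db_id=f"db{i}",
                n_patients=n_per_db if i != 1 else int(n_per_db * 1.25),
                age_mean=float(age_means[i]),
                age_sd=12.0,
                age_min=18.0,
                age_max=65.0 if is_trunc else 94.9,
                male_fraction=float(rng.uniform(0.25, 0.35)),
                prevalence_shift=rng.normal(0.0, 0.4, size=n_features),
                intercept_shift=float(intercept_shifts[i]),
                sample_cap=n_per_db if i == 1 else None,
            )
        )
    return profiles, truth


def homogeneous_scenario(
    n_databases: int, n_features: int, seed: int, n_per_db: int = 20_000
) -> tuple[list[DatabaseProfile], GroundTruth]:
    """Databases drawn i.i.d. from a single profile (no heterogeneity).

    In this world every method's external performance should match the
    internal benchmark up to sampling noise — the consistency check for the
    leave-one-database-out machinery.
    """
    if n_databases < 2:
        raise InvalidScenarioError("need at least 2 databases")
    if n_features < 5:
        raise InvalidScenarioError("need at least 5 condition/drug features")
    rng = np.random.default_rng(seed)
    truth = _build_truth(n_features, rng)
    shared_shift = np.zeros(n_features)
    profiles = [
        DatabaseProfile(
            db_id=f"db{i}",
            n_patients=n_per_db,
            age_mean=52.0,
            age_sd=14.0,
            age_min=18.0,
            age_max=94.9,
            male_fraction=0.3,
            prevalence_shift=shared_shift,
            intercept_shift=0.0,
        )
        for i in range(n_databases)
    ]
    return profiles, truth


def simulate_database(
    profile: DatabaseProfile, truth: GroundTruth, seed: int
) -> LabelledDataset:
    """Draw one database from the shared generating process.

    Ages are truncated-normal; condition/drug indicators are independent
    Bernoulli with logit-shifted prevalences; age-bin and gender indicators
    are derived; labels follow ``P(y=1|x) = expit(beta0 + intercept_shift +
    x.beta)``.  Fully reproducible given the seed.
    """
    n_cond = truth.n_condition_features
    if n_cond == 0:
        raise InvalidScenarioError("truth has no condition/drug features")
    if len(profile.prevalence_shift) != n_cond:
        raise InvalidScenarioError("prevalence_shift length does not match truth")

    n = profile.effective_n
    rng = np.random.default_rng(seed)

    a = (profile.age_min - profile.age_mean) / profile.age_sd
    b = (profile.age_max - profile.age_mean) / profile.age_sd
    age_years = truncnorm.rvs(
        a, b, loc=profile.age_mean, scale=profile.age_sd, size=n, random_state=rng
    )

    cond_p = expit(logit(truth.baseline_prevalence[:n_cond]) + profile.prevalence_shift)
    cond = (rng.random((n, n_cond)) < cond_p).astype(np.uint8)

    bins = age_bin_index(age_years)
    age_onehot = np.zeros((n, N_AGE_BINS), dtype=np.uint8)
    age_onehot[np.arange(n), bins] = 1

    male = (rng.random(n) < profile.male_fraction).astype(np.uint8)

    x = np.hstack([cond, age_onehot, male[:, None]])
    features = pd.DataFrame(x, columns=list(truth.feature_names))

    lp = x @ truth.beta
    labels = {}
    for outcome in truth.outcome_ids:
        p = expit(truth.beta0[outcome] + profile.intercept_shift + lp)
        labels[outcome] = (rng.random(n) < p).astype(np.uint8)

    return LabelledDataset(
        db_id=profile.db_id, features=features, age_years=age_years, labels=labels
    )


def simulate_scenario(
    profiles: list[DatabaseProfile], truth: GroundTruth, seed: int
) -> list[LabelledDataset]:
    """Simulate every database of a scenario with per-database derived seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(profiles))
    return [
        simulate_database(p, truth, int(c.generate_state(1)[0] % 2**31))
        for p, c in zip(profiles, children)
    ]


def population_feature_means(ds: LabelledDataset, feature_subset) -> np.ndarray:
    """Per-column means over the dataset rows, ordered as ``feature_subset``."""
    subset = list(feature_subset)
    if not subset:
        raise ValueError("feature_subset must be non-empty (cosine undefined on empty vectors)")
    missing = [c for c in subset if c not in ds.features.columns]
    if missing:
        raise KeyError(f"columns not in dataset: {missing}")
    return ds.features[subset].to_numpy(dtype=float).mean(axis=0)
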