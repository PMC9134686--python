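import numpy as np
import pandas as pd
import pytest

from riskfusion import lodo, simdata
from riskfusion.level1 import Level1Model, ModelCard
from riskfusion.simdata import LabelledDataset

# One experiment seed pinned for every seeded fixture and regression check.
PINNED_SEED = 7


def make_dataset(
    db_id="dbx",
    n=400,
    n_features=4,
    event_rate=0.2,
    seed=0,
    age_mean=50.0,
    outcome_id="y",
):
    """Small hand-rolled database: independent binary features, one outcome."""
    rng = np.random.default_rng(seed)
    feats = pd.DataFrame(
        rng.integers(0, 2, size=(n, n_features)).astype(np.uint8),
        columns=[f"feat_{i:03d}" for i in range(n_features)],
    )
    ages = rng.normal(age_mean, 10.0, size=n).clip(18, 90)
    y = (rng.random(n) < event_rate).astype(np.uint8)
    return LabelledDataset(db_id=db_id, features=feats, age_years=ages, labels={outcome_id: y})


def make_card(
    db_id,
    auroc=0.7,
    dev_mean_age=50.0,
    coefficients=None,
    feature_names=("feat_000", "feat_001"),
    dev_feature_means=None,
    intercept=0.0,
    outcome_id="y",
):
    """Model card with prescribed summaries, bypassing training."""
    coefficients = (
        np.asarray(coefficients, dtype=float)
        if coefficients is not None
        else np.ones(len(feature_names))
    )
    model = Level1Model(
        db_id=db_id,
        outcome_id=outcome_id,
        coefficients=coefficients,
        intercept=intercept,
        penalty=1.0,
        feature_names=tuple(feature_names),
    )
    included = model.included_features
    if dev_feature_means is None:
        dev_feature_means = {n: 0.5 for n in included}
    return ModelCard(
        model=model,
        internal_auroc=auroc,
        internal_citl=0.0,
        internal_gradient=1.0,
        dev_feature_means=dev_feature_means,
        dev_mean_age=dev_mean_age,
        dev_outcome_rate=0.1,
        train_n=100,
        test_n=25,
        degenerate=len(included) == 0,
    )


@pytest.fixture(scope="session")
def hetero_frame():
    """Default heterogeneous scenario, full leave-one-database-out run."""
    profiles, truth = simdata.default_scenario(5, 50, seed=PINNED_SEED)
    datasets = simdata.simulate_scenario(profiles, truth, seed=PINNED_SEED)
    results = lodo.run_lodo(datasets, lodo.ExperimentConfig(seed=PINNED_SEED))
    return lodo.results_to_frame(results)


@pytest.fixture(scope="session")
def homog_frame():
    """Five i.i.d. databases from one profile, common outcome only."""
    profiles, truth = simdata.homogeneous_scenario(5, 50, seed=PINNED_SEED)
    datasets = simdata.simulate_scenario(profiles, truth, seed=PINNED_SEED)
    config = lodo.ExperimentConfig(seed=PINNED_SEED, outcomes=("common",))
    return lodo.results_to_frame(lodo.run_lodo(datasets, config))
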