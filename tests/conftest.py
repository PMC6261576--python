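import numpy as np
import pandas as pd
import pytest

from arstrat.cohort import BINARY_COVARIATES, COLUMNS, SYMPTOM_ITEMS, Cohort
from arstrat.pipeline import compute_labelings
from arstrat.synthetic import GeneratorConfig, generate_cohort


def build_cohort(symptoms, vas=None, ids=None, **overrides) -> Cohort:
    """Assemble a valid Cohort from an n x 17 Likert matrix.

    Covariates default to fixed benign values; pass overrides as
    column -> array.  ``vas`` defaults to 50 for every patient.
    """
    symptoms = np.asarray(symptoms, dtype=float)
    n = symptoms.shape[0]
    assert symptoms.shape == (n, 17)
    data = {"id": ids if ids is not None else [f"T{i}" for i in range(n)]}
    for j, item in enumerate(SYMPTOM_ITEMS):
        data[item] = symptoms[:, j]
    data["vas"] = np.full(n, 50.0) if vas is None else np.asarray(vas, dtype=float)
    data["age"] = np.full(n, 30.0)
    data["sex"] = ["F"] * n
    data["onset"] = np.full(n, 5.0)
    data["episode_duration"] = np.full(n, 10.0)
    for col in BINARY_COVARIATES:
        data[col] = np.zeros(n)
    data["region"] = np.ones(n)
    data.update(overrides)
    return Cohort(pd.DataFrame(data).loc[:, list(COLUMNS)], provenance="test")


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort at desk scale (n=1100)."""
    cfg = GeneratorConfig(n=1100, seed=2024)
    cohort, classes = generate_cohort(cfg)
    return cohort, classes, cfg


@pytest.fixture(scope="session")
def analysis_bundle(default_cohort):
    """Complete cases of the default cohort with the five labelings."""
    from arstrat.cohort import filter_complete_cases

    cohort, classes, cfg = default_cohort
    retained, _ = filter_complete_cases(cohort)
    keep = ~cohort.incomplete_mask()
    labelings, scores, std = compute_labelings(retained, seed=cfg.seed)
    return {
        "retained": retained,
        "true_classes": classes[keep],
        "labelings": labelings,
        "scores": scores,
        "std": std,
    }


@pytest.fixture(scope="session")
def recovery_cohort():
    """Large complete-case cohort for latent-class recovery checks."""
    cfg = GeneratorConfig(n=10_000, missing_rate=0.0, seed=77)
    cohort, classes = generate_cohort(cfg)
    return cohort, classes
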