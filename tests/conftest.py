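"""Shared fixtures: small synthetic cohorts, planted feature tables, and
walk segments with ground truth."""

import numpy as np
import pytest

from stablegait.synth import CohortSpec, GroupParams, generate_cohort, \
    generate_feature_table


def small_cohort_spec(seed: int = 0) -> CohortSpec:
    """A reduced three-group cohort for fast pipeline-level tests."""
    spec = CohortSpec(seed=seed)
    g = spec.groups
    spec.groups = {
        "YA": GroupParams(8, *[getattr(g["YA"], f) for f in (
            "age_range", "age_mean", "age_sd", "mdcog_mean", "mdcog_sd",
            "height_mean", "height_sd", "weight_mean", "weight_sd",
            "female_frac")]),
        "HE": GroupParams(12, *[getattr(g["HE"], f) for f in (
            "age_range", "age_mean", "age_sd", "mdcog_mean", "mdcog_sd",
            "height_mean", "height_sd", "weight_mean", "weight_sd",
            "female_frac")]),
        "MCI-E": GroupParams(8, *[getattr(g["MCI-E"], f) for f in (
            "age_range", "age_mean", "age_sd", "mdcog_mean", "mdcog_sd",
            "height_mean", "height_sd", "weight_mean", "weight_sd",
            "female_frac")]),
    }
    return spec


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def elderly_cohort():
    """62 HE + 23 MCI-E, the discrimination of interest."""
    cohort = generate_cohort(CohortSpec(seed=1))
    return [s for s in cohort if s.group in ("HE", "MCI-E")]


@pytest.fixture(scope="session")
def planted_table(elderly_cohort):
    """96-column table with three planted features at d = 2."""
    return generate_feature_table(elderly_cohort,
                                  planted_features=(3, 40, 77),
                                  effect_size=2.0, seed=7)


@pytest.fixture(scope="session")
def noise_table(elderly_cohort):
    return generate_feature_table(elderly_cohort, seed=11)


def match_events(detected: np.ndarray, truth: np.ndarray,
                 t_end: float, edge: float = 2.0):
    """Compare detected event times with ground truth away from edges.

    Windows are anchored at midpoints between ground-truth events so no
    event sits on a window boundary.  Returns (n_truth, n_detected,
    per-event absolute errors) for the interior events.
    """
    k = np.searchsorted(truth, edge)
    k2 = np.searchsorted(truth, t_end - edge)
    inner = truth[k + 1:k2 - 1]
    lo = (truth[k] + truth[k + 1]) / 2
    hi = (truth[k2 - 2] + truth[k2 - 1]) / 2
    det = detected[(detected > lo) & (detected < hi)]
    errors = np.array([np.min(np.abs(detected - t)) for t in inner])
    return len(inner), len(det), errors
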