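"""Synthetic neuropsychological score tables with a controllable MDCog.

Twelve test measures (global cognition, attention, processing speed,
executive function, verbal memory) are generated as linear functions of
age and education plus correlated residual noise.  The residual of each
subject is built in the whitened (Mahalanobis) space of the normative
covariance, so the population Mahalanobis distance of every subject is
known exactly and the three study groups can be given distinct MDCog
distributions.

Residual model, in whitened coordinates (e1 = impairment direction):

    w = (shift_g + axial_g * zeta) * e1 + rho_g * z,   zeta ~ N(0,1),
                                                        z ~ N(0, I_12)

``shift`` moves a group coherently toward worse performance (non-zero only
for the impaired group by default), ``axial`` spreads subjects along that
direction (severity heterogeneity) and ``rho`` scales the isotropic part.
The default constants below were solved numerically (method of moments,
large-sample Monte Carlo) so that the population MDCog mean and SD equal
the study targets: YA 2.91 +/- 0.97, HE 3.81 +/- 1.08, MCI-E 9.30 +/- 1.65.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import SubjectRecord

# name, higher_is_worse, baseline, unit scale, age slope, education slope
# (slopes are on the standardized deficit scale, per year)
MEASURE_DEFS = [
    ("MMSE", False, 28.0, 1.5, 0.020, -0.030),
    ("BTA_numbers", False, 8.5, 1.2, 0.022, -0.028),
    ("BTA_letters", False, 8.0, 1.2, 0.022, -0.028),
    ("TMT_A", True, 45.0, 15.0, 0.030, -0.035),
    ("TMT_B", True, 110.0, 35.0, 0.032, -0.040),
    ("TMT_B_minus_A", True, 65.0, 25.0, 0.028, -0.030),
    ("HVLT_immediate", False, 26.0, 4.0, 0.026, -0.025),
    ("HVLT_delayed", False, 9.0, 2.0, 0.028, -0.022),
    ("HVLT_retention", False, 90.0, 10.0, 0.024, -0.018),
    ("HVLT_recognition", False, 11.0, 1.0, 0.020, -0.015),
    ("DS_symbols", False, 45.0, 10.0, 0.034, -0.045),
    ("DS_recall", False, 7.0, 1.5, 0.022, -0.030),
]
MEASURES = [m[0] for m in MEASURE_DEFS]
LOWER_BETTER = [m[0] for m in MEASURE_DEFS if m[1]]
N_MEASURES = len(MEASURES)

AGE_CENTER, EDU_CENTER = 45.0, 12.0

# (shift, axial, rho) per group, solved against the MDCog targets above
MDCOG_SEVERITY = {
    "YA": (0.0, 2.0768, 0.6518),
    "HE": (0.0, 2.3064, 0.9293),
    "MCI-E": (8.6651, 1.4435, 1.0),
}


def default_residual_correlation(rho: float = 0.3) -> np.ndarray:
    """Compound-symmetric correlation among the 12 measure residuals."""
    C = np.full((N_MEASURES, N_MEASURES), rho)
    np.fill_diagonal(C, 1.0)
    return C


def _chol(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (N_MEASURES, N_MEASURES):
        raise ValueError(f"covariance must be {N_MEASURES}x{N_MEASURES}")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise covariance is not positive definite") from exc


def default_effect(magnitude: float | None = None) -> np.ndarray:
    """Mean MCI-E residual shift on the oriented (deficit) scale.

    The impairment direction is the first whitened coordinate mapped back
    through the Cholesky factor of the default residual correlation; its
    length defaults to the calibrated severity shift.
    """
    L = _chol(default_residual_correlation())
    if magnitude is None:
        magnitude = MDCOG_SEVERITY["MCI-E"][0]
    return magnitude * L[:, 0]


def _deficit_to_raw(deficit: np.ndarray) -> np.ndarray:
    """Map standardized deficit values to raw measure units."""
    raw = np.empty_like(deficit)
    for j, (_, higher_worse, base, scale, _, _) in enumerate(MEASURE_DEFS):
        sign = 1.0 if higher_worse else -1.0
        raw[:, j] = base + sign * scale * deficit[:, j]
    return raw


def _age_edu_deficit(age: np.ndarray, edu: np.ndarray) -> np.ndarray:
    out = np.empty((len(age), N_MEASURES))
    for j, (_, _, _, _, ba, be) in enumerate(MEASURE_DEFS):
        out[:, j] = ba * (age - AGE_CENTER) + be * (edu - EDU_CENTER)
    return out


def generate_cognitive_scores(cohort: list[SubjectRecord],
                              effect: np.ndarray | None = None,
                              noise_cov: np.ndarray | None = None,
                              seed: int | None = 0) -> pd.DataFrame:
    """Cognitive score table for a cohort, with group-dependent residuals.

    Parameters
    ----------
    cohort : list of SubjectRecord
    effect : array (12,), optional
        Mean residual shift of the MCI-E group on the standardized deficit
        scale (positive = worse).  When omitted the calibrated study-mode
        machinery is used: per-group (shift, axial, rho) severity so the
        MDCog distributions match the study targets.  When given, a plain
        additive model is used: residual = 1[MCI-E] * effect + MVN noise.
    noise_cov : array (12, 12), optional
        Residual covariance on the deficit scale (default: unit variances
        with compound-symmetric correlation 0.3).  Must be positive
        definite.
    seed : int

    Returns
    -------
    DataFrame indexed by subject id with the 12 measure columns (raw
    units) plus ``age`` and ``education``.
    """
    rng = np.random.default_rng(seed)
    cov = default_residual_correlation() if noise_cov is None else noise_cov
    L = _chol(cov)
    age = np.array([s.age for s in cohort], dtype=float)
    edu = np.array([s.education for s in cohort], dtype=float)
    groups = np.array([s.group for s in cohort])
    n = len(cohort)
    z = rng.standard_normal((n, N_MEASURES))
    zeta = rng.standard_normal(n)
    resid = np.empty((n, N_MEASURES))
    if effect is None:
        for g, (shift, axial, rho) in MDCOG_SEVERITY.items():
            m = groups == g
            if not m.any():
                continue
            w = rho * z[m]
            w[:, 0] += shift + axial * zeta[m]
            resid[m] = w @ L.T
        resid[~np.isin(groups, list(MDCOG_SEVERITY))] = 0.0
    else:
        effect = np.asarray(effect, dtype=float)
        if effect.shape != (N_MEASURES,):
            raise ValueError(f"effect must have length {N_MEASURES}")
        resid = z @ L.T
        resid[groups == "MCI-E"] += effect
    deficit = _age_edu_deficit(age, edu) + resid
    raw = _deficit_to_raw(deficit)
    df = pd.DataFrame(raw, columns=MEASURES,
                      index=pd.Index([s.id for s in cohort], name="id"))
    df["age"] = age
    df["education"] = edu
    return df


def generate_normative_scores(n: int = 300, seed: int | None = 0,
                              age_range: tuple[float, float] = (20.0, 90.0),
                              edu_range: tuple[int, int] = (6, 20)
                              ) -> pd.DataFrame:
    """Normative reference sample: standard residuals, broad age/education.

    Residuals are exactly N(0, Sigma) on the deficit scale, so a normative
    model fitted on this table recovers the generating coefficients and
    covariance as the sample grows.
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(*age_range, size=n)
    edu = rng.integers(edu_range[0], edu_range[1] + 1, size=n).astype(float)
    L = _chol(default_residual_correlation())
    resid = rng.standard_normal((n, N_MEASURES)) @ L.T
    raw = _deficit_to_raw(_age_edu_deficit(age, edu) + resid)
    df = pd.DataFrame(raw, columns=MEASURES,
                      index=pd.Index([f"NORM{i + 1:04d}" for i in range(n)],
                                     name="id"))
    df["age"] = age
    df["education"] = edu
    return df
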