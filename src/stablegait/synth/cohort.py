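"""Synthetic study cohorts: young adults, healthy and impaired elderly.

The default parameterization reproduces the demographic structure of the
three-group design this package targets: 40 young adults (YA, ages 22-38),
62 healthy elderly (HE) and 23 cognitively impaired elderly (MCI-E), both
elderly groups aged 60+, with group-specific height, weight and summary
cognitive-index (MDCog) distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("YA", "HE", "MCI-E")


@dataclass(frozen=True)
class GroupParams:
    """Demographic and cognitive-index parameters of one study group."""

    n: int
    age_range: tuple[float, float]
    age_mean: float
    age_sd: float
    mdcog_mean: float
    mdcog_sd: float
    height_mean: float
    height_sd: float
    weight_mean: float
    weight_sd: float
    female_frac: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be non-negative")
        for sd in (self.age_sd, self.mdcog_sd, self.height_sd, self.weight_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age range must be non-empty")


def _default_groups() -> dict[str, GroupParams]:
    return {
        "YA": GroupParams(40, (22.0, 38.0), 27.65, 4.14, 2.91, 0.97,
                          167.97, 8.19, 70.20, 14.69, 0.50),
        "HE": GroupParams(62, (60.0, 88.0), 72.23, 6.59, 3.81, 1.08,
                          161.57, 9.92, 68.47, 16.59, 0.597),
        "MCI-E": GroupParams(23, (61.0, 87.0), 76.00, 7.43, 9.30, 1.65,
                             159.69, 8.95, 64.13, 14.63, 0.695),
    }


@dataclass
class CohortSpec:
    """Cohort recipe; defaults reproduce the three-group study design."""

    groups: dict[str, GroupParams] = field(default_factory=_default_groups)
    education_range: tuple[int, int] = (6, 20)
    seed: int = 0

    @property
    def n_ya(self) -> int:
        return self.groups["YA"].n

    @property
    def n_he(self) -> int:
        return self.groups["HE"].n

    @property
    def n_mcie(self) -> int:
        return self.groups["MCI-E"].n


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    group: str
    age: float
    sex: str
    height: float
    weight: float
    education: int


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    """Normal draws rejected outside [lo, hi] (narrow tails, cheap)."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def generate_cohort(spec: CohortSpec | None = None,
                    seed: int | None = None) -> list[SubjectRecord]:
    """Draw a deterministic synthetic cohort from a :class:`CohortSpec`.

    Ages, heights and weights are truncated normals inside each group's
    stated range; education is uniform over ``spec.education_range`` and
    independent of group.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subjects: list[SubjectRecord] = []
    for group in GROUPS:
        if group not in spec.groups:
            continue
        g = spec.groups[group]
        ages = _trunc_normal(rng, g.age_mean, g.age_sd, *g.age_range, size=g.n)
        heights = _trunc_normal(rng, g.height_mean, g.height_sd,
                                g.height_mean - 3.5 * g.height_sd,
                                g.height_mean + 3.5 * g.height_sd, size=g.n)
        weights = _trunc_normal(rng, g.weight_mean, g.weight_sd,
                                max(35.0, g.weight_mean - 3.5 * g.weight_sd),
                                g.weight_mean + 3.5 * g.weight_sd, size=g.n)
        sexes = np.where(rng.random(g.n) < g.female_frac, "F", "M")
        edu = rng.integers(spec.education_range[0],
                           spec.education_range[1] + 1, size=g.n)
        tag = group.replace("-", "")
        for i in range(g.n):
            subjects.append(SubjectRecord(
                id=f"{tag}{i + 1:03d}", group=group, age=float(ages[i]),
                sex=str(sexes[i]), height=float(heights[i]),
                weight=float(weights[i]), education=int(edu[i])))
    return subjects


def cohort_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame indexed by subject id."""
    df = pd.DataFrame([s.__dict__ for s in subjects]).set_index("id")
    return df
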