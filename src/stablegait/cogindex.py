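"""Summary cognitive index (MDCog) and data-driven group definition.

MDCog condenses a battery of neuropsychological measures into a single
non-negative score: each measure is adjusted for age and education by
linear regression against a normative sample, residuals are oriented so
that larger means worse performance, and the subject's score is the
Mahalanobis distance of the oriented residual vector from the normative
origin, using the normative residual covariance.  Larger MDCog = larger
overall deviation from normative cognition.

Groups are then defined by one-dimensional k-means (k=2, many restarts)
on MDCog — the higher-centroid cluster is the impaired group — and the
healthy cluster is split by age into young and elderly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CognitiveNormativeModel",
    "NormativeResults",
    "fit_normative_model",
    "compute_mdcog",
    "GroupLabels",
    "cluster_groups",
]

DEFAULT_LOWER_BETTER = ("TMT_A", "TMT_B", "TMT_B_minus_A")


class CognitiveNormativeModel:
    """Normative age/education adjustment model for a score battery.

    Parameters
    ----------
    scores : DataFrame
        Normative sample; one row per subject with the measure columns
        plus ``age`` and ``education``.
    measures : sequence of str, optional
        Measure column names (default: every column except age/education).
    lower_better : sequence of str, optional
        Measures where a *lower* raw score means better performance
        (e.g. timed tests); these are negated before orientation so that
        "worse" is a consistent direction across measures.
    """

    def __init__(self, scores: pd.DataFrame, measures=None, lower_better=None):
        if measures is None:
            measures = [c for c in scores.columns
                        if c not in ("age", "education")]
        self.measures = list(measures)
        self.lower_better = tuple(
            m for m in (DEFAULT_LOWER_BETTER if lower_better is None
                        else lower_better) if m in self.measures)
        missing = [c for c in (*self.measures, "age", "education")
                   if c not in scores.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if scores[self.measures + ["age", "education"]].isna().any().any():
            raise ValueError("missing values are not accepted")
        if len(scores) < 30:
            raise ValueError("need at least 30 normative subjects")
        self.scores = scores

    def _oriented(self, scores: pd.DataFrame) -> np.ndarray:
        """Measures on the deficit scale (higher = worse)."""
        Y = scores[self.measures].to_numpy(dtype=float).copy()
        for j, m in enumerate(self.measures):
            if m not in self.lower_better:
                Y[:, j] = -Y[:, j]
        return Y

    def fit(self, shrink_condition: float = 1e6) -> "NormativeResults":
        """Per-measure OLS on age and education; pooled residual covariance.

        The covariance is shrunk toward its diagonal with an analytic
        (Schafer-Strimmer type) intensity when its condition number
        exceeds ``shrink_condition``.
        """
        X = sm.add_constant(
            self.scores[["age", "education"]].to_numpy(dtype=float),
            has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design: age/education not varying")
        Y = self._oriented(self.scores)
        coefs = np.empty((len(self.measures), 3))
        resid = np.empty_like(Y)
        for j in range(Y.shape[1]):
            res = sm.OLS(Y[:, j], X).fit()
            coefs[j] = res.params
            resid[:, j] = res.resid
        dof = len(Y) - X.shape[1]
        cov = resid.T @ resid / dof
        shrinkage = 0.0
        if np.linalg.cond(cov) > shrink_condition:
            cov, shrinkage = _shrink_to_diagonal(resid, cov)
        return NormativeResults(model=self, coef=coefs, resid_cov=cov,
                                n_obs=len(Y), shrinkage=shrinkage)


def _shrink_to_diagonal(resid: np.ndarray, cov: np.ndarray):
    """Diagonal-target linear shrinkage with analytic intensity.

    Intensity = sum of estimation variances of the off-diagonal entries
    over the sum of their squares, clipped to [0, 1].
    """
    n = len(resid)
    Xc = resid - resid.mean(axis=0)
    w = np.einsum("ti,tj->tij", Xc, Xc)
    var_s = w.var(axis=0, ddof=1) * n / (n - 1) ** 2
    off = ~np.eye(cov.shape[0], dtype=bool)
    denom = (cov[off] ** 2).sum()
    lam = float(np.clip(var_s[off].sum() / denom if denom > 0 else 1.0,
                        0.0, 1.0))
    target = np.diag(np.diag(cov))
    return (1 - lam) * cov + lam * target, lam


@dataclass
class NormativeResults:
    """Fitted normative model: adjustment coefficients plus covariance."""

    model: CognitiveNormativeModel
    coef: np.ndarray          # (n_measures, 3): const, age, education
    resid_cov: np.ndarray     # (n_measures, n_measures), positive definite
    n_obs: int
    shrinkage: float = 0.0
    _cov_inv: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self._cov_inv = np.linalg.inv(self.resid_cov)

    def residuals(self, scores: pd.DataFrame) -> np.ndarray:
        """Oriented residuals (observed deficit minus age/edu prediction)."""
        m = self.model
        if scores[m.measures].isna().any().any():
            raise ValueError("missing values are not accepted into MDCog")
        Y = m._oriented(scores)
        X = sm.add_constant(
            scores[["age", "education"]].to_numpy(dtype=float),
            has_constant="add")
        return Y - X @ self.coef.T

    def mahalanobis(self, scores: pd.DataFrame) -> pd.Series:
        """MDCog for each row: sqrt(r' Sigma^-1 r) of oriented residuals."""
        R = self.residuals(scores)
        d2 = np.einsum("ij,jk,ik->i", R, self._cov_inv, R)
        return pd.Series(np.sqrt(np.maximum(d2, 0.0)), index=scores.index,
                         name="MDCog")

    def summary(self) -> str:
        lines = [f"Normative model: {len(self.model.measures)} measures, "
                 f"n={self.n_obs}, covariance shrinkage={self.shrinkage:.3f}",
                 f"{'measure':<18}{'const':>10}{'age':>10}{'education':>12}"]
        for m, c in zip(self.model.measures, self.coef):
            lines.append(f"{m:<18}{c[0]:>10.3f}{c[1]:>10.4f}{c[2]:>12.4f}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "measures": self.model.measures,
            "lower_better": list(self.model.lower_better),
            "coef": self.coef.tolist(),
            "resid_cov": self.resid_cov.tolist(),
            "n_obs": self.n_obs,
            "shrinkage": self.shrinkage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormativeResults":
        with open(path) as fh:
            payload = json.load(fh)
        model = CognitiveNormativeModel.__new__(CognitiveNormativeModel)
        model.measures = payload["measures"]
        model.lower_better = tuple(payload["lower_better"])
        model.scores = None
        return cls(model=model, coef=np.array(payload["coef"]),
                   resid_cov=np.array(payload["resid_cov"]),
                   n_obs=payload["n_obs"], shrinkage=payload["shrinkage"])


def fit_normative_model(scores: pd.DataFrame, **kwargs) -> NormativeResults:
    """Convenience wrapper: build and fit the normative model."""
    return CognitiveNormativeModel(scores, **kwargs).fit()


def compute_mdcog(scores: pd.DataFrame, results: NormativeResults) -> pd.Series:
    """MDCog index for one or more subjects under a fitted model."""
    return results.mahalanobis(scores)


def _kmeans_1d(x: np.ndarray, k: int, repeats: int,
               rng: np.random.Generator, n_iter: int = 100):
    """Lloyd's algorithm on a 1-D sample, vectorized across restarts.

    Initial centers are sampled from the data points; the restart with the
    lowest within-cluster sum of squares wins.
    """
    n = len(x)
    centers = x[rng.integers(0, n, size=(repeats, k))]
    centers += rng.normal(0, 1e-9 * (x.std() + 1), size=centers.shape)
    for _ in range(n_iter):
        assign = np.abs(x[None, :, None] - centers[:, None, :]).argmin(axis=2)
        new = np.empty_like(centers)
        for j in range(k):
            mask = assign == j
            cnt = mask.sum(axis=1)
            s = np.where(mask, x[None, :], 0.0).sum(axis=1)
            with np.errstate(invalid="ignore"):
                new[:, j] = np.where(cnt > 0, s / np.maximum(cnt, 1),
                                     centers[:, j])
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    assign = np.abs(x[None, :, None] - centers[:, None, :]).argmin(axis=2)
    inertia = ((x[None, :] - np.take_along_axis(
        centers, assign, axis=1)) ** 2).sum(axis=1)
    best = int(inertia.argmin())
    return centers[best], assign[best], float(inertia[best])


@dataclass
class GroupLabels:
    """Result of MDCog clustering plus the age split."""

    labels: pd.Series             # subject id -> {YA, HE, MCI-E}
    centroids: np.ndarray         # sorted ascending (healthy, impaired)
    boundary: float               # midpoint between the two centroids
    inertia: float
    repeats: int

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def cluster_groups(mdcog: pd.Series, ages: pd.Series, k: int = 2,
                   repeats: int = 1000, age_threshold: float = 60.0,
                   seed: int | None = 0) -> GroupLabels:
    """Define YA / HE / MCI-E from MDCog k-means and an age split.

    One-dimensional k-means (``repeats`` random restarts, best inertia
    kept) separates healthy from impaired; within the healthy cluster,
    subjects younger than ``age_threshold`` are YA, the rest HE.
    """
    x = np.asarray(mdcog, dtype=float)
    if len(np.unique(x)) < k:
        raise ValueError("need at least k distinct MDCog values")
    ages = np.asarray(ages, dtype=float)
    order_index = mdcog.index if isinstance(mdcog, pd.Series) \
        else pd.RangeIndex(len(x))
    rng = np.random.default_rng(seed)
    centers, assign, inertia = _kmeans_1d(x, k, repeats, rng)
    order = np.argsort(centers)
    impaired_cluster = order[-1]
    labels = np.where(assign == impaired_cluster, "MCI-E",
                      np.where(ages < age_threshold, "YA", "HE"))
    return GroupLabels(labels=pd.Series(labels, index=order_index,
                                        name="group"),
                       centroids=np.sort(centers),
                       boundary=float(np.sort(centers)[-2:].mean()),
                       inertia=inertia, repeats=repeats)
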