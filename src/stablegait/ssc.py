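"""Stable Sparse Classifiers: resampled elastic-net biomarker selection
with ROC-distribution validation.

The procedure has two stages:

1. *Selection.*  In each of ``n_iter`` iterations a stratified 70 %
   subject subsample and a random 70 % feature subsample are drawn, a
   univariate screening step removes low-contribution features, and a
   penalized (elastic-net) linear model with an internally
   cross-validated lambda is fitted.  A feature counts as selected when
   its coefficient is non-zero; its selection frequency is the fraction
   of iterations *in which it was offered* (survived the feature
   subsample and screening) where it was selected.  Features with
   frequency above the consistency threshold (50 %) form the stable set.

2. *Validation.*  With features restricted to the stable set, repeated
   stratified 70/30 splits refit the model on the training part and
   score the held-out subjects; the distribution of the resulting
   ROC/AUC values summarizes out-of-sample performance, reported at its
   median, with pointwise 95 % ROC bands and an operating point at a
   fixed target sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .enet import ElasticNetConfig, cv_select_lambda, elastic_net_fit

__all__ = [
    "screen_features",
    "StableSparseClassifier",
    "StabilityResult",
    "ValidationResult",
    "OperatingPoint",
    "validate_model",
    "operating_point",
]


def screen_features(X: np.ndarray, y: np.ndarray,
                    keep_fraction: float = 0.5) -> np.ndarray:
    """Keep the top fraction of features by absolute two-sample t statistic.

    Zero-variance features rank last.  Returns sorted column indices.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("screening requires exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.abs(np.where(np.isfinite(t), t, 0.0))
    n_keep = max(int(np.ceil(keep_fraction * X.shape[1])), 1)
    order = np.argsort(-t, kind="stable")
    return np.sort(order[:n_keep])


def _stratified_subsample(y: np.ndarray, fraction: float,
                          rng: np.random.Generator,
                          max_retries: int = 20) -> np.ndarray:
    """Index subsample keeping both classes, class-proportional sizes."""
    for _ in range(max_retries):
        idx = []
        for value in np.unique(y):
            members = np.flatnonzero(y == value)
            k = max(int(round(fraction * len(members))), 1)
            idx.append(rng.choice(members, size=k, replace=False))
        idx = np.sort(np.concatenate(idx))
        if len(np.unique(y[idx])) >= 2:
            return idx
    raise RuntimeError("could not draw a two-class subsample")


class StableSparseClassifier:
    """Stable sparse classification of a binary outcome from a feature
    table.

    Parameters
    ----------
    X : array (n, p) or DataFrame
        Feature matrix; column names are kept for reporting.
    y : array (n,)
        Binary labels (any two values; the larger-coded class is treated
        as positive).
    config : ElasticNetConfig, optional
        Penalized-model settings (mixing gamma, lambda path, internal
        CV folds).
    n_iter, subject_fraction, feature_fraction, threshold, keep_fraction
        Resampling protocol of the selection stage.

    Examples
    --------
    >>> model = StableSparseClassifier(X, y)
    >>> sel = model.fit(seed=0)
    >>> val = sel.validate(seed=1)
    >>> print(sel.summary()); print(val.summary())
    """

    def __init__(self, X, y, config: ElasticNetConfig | None = None,
                 n_iter: int = 500, subject_fraction: float = 0.7,
                 feature_fraction: float = 0.7, threshold: float = 0.5,
                 keep_fraction: float = 0.5):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{j}" for j in range(X.shape[1])]
        if not np.isfinite(X).all():
            raise ValueError("non-finite entries in X")
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("y must contain exactly two classes")
        if X.shape[1] < 2:
            raise ValueError("need at least two features")
        self.X = X
        self.y01 = (y == classes[1]).astype(float)
        self.classes = classes
        self.config = config or ElasticNetConfig()
        self.n_iter = n_iter
        self.subject_fraction = subject_fraction
        self.feature_fraction = feature_fraction
        self.threshold = threshold
        self.keep_fraction = keep_fraction

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, label_column: str = "label",
                       positive: str | None = None, **kw
                       ) -> "StableSparseClassifier":
        """Build from a feature table carrying a label column."""
        y = table[label_column].to_numpy()
        X = table.drop(columns=[label_column])
        if positive is not None:
            y = np.where(y == positive, 1, 0)
        return cls(X, y, **kw)

    def fit(self, seed: int | None = 0) -> "StabilityResult":
        """Run the resampled selection stage."""
        n, p = self.X.shape
        rng = np.random.default_rng(seed)
        n_feat = max(int(round(self.feature_fraction * p)), 2)
        offered = np.zeros(p)
        selected = np.zeros(p)
        for _ in range(self.n_iter):
            subj = _stratified_subsample(self.y01, self.subject_fraction, rng)
            feat = np.sort(rng.choice(p, size=n_feat, replace=False))
            Xs, ys = self.X[np.ix_(subj, feat)], self.y01[subj]
            keep_rel = screen_features(Xs, ys, self.keep_fraction)
            feat = feat[keep_rel]
            Xs = Xs[:, keep_rel]
            sd = Xs.std(axis=0)
            ok = sd > 0
            feat, Xs = feat[ok], Xs[:, ok]
            offered[feat] += 1
            lam, _, _ = cv_select_lambda(Xs, ys, self.config, seed=rng)
            fit = elastic_net_fit(Xs, ys, self.config, lam)
            selected[feat[fit.support]] += 1
        with np.errstate(invalid="ignore"):
            freq = np.where(offered > 0, selected / np.maximum(offered, 1),
                            0.0)
        stable = np.flatnonzero(freq > self.threshold)
        return StabilityResult(model=self, frequencies=freq,
                               stable_set=stable, n_iter=self.n_iter,
                               offered=offered, seed=seed)


@dataclass
class StabilityResult:
    """Selection frequencies and the stable biomarker set."""

    model: StableSparseClassifier
    frequencies: np.ndarray
    stable_set: np.ndarray
    n_iter: int
    offered: np.ndarray
    seed: int | None

    @property
    def stable_features(self) -> list[str]:
        return [self.model.feature_names[j] for j in self.stable_set]

    def frequency_table(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "feature": self.model.feature_names,
            "frequency": self.frequencies,
            "offered": self.offered.astype(int),
            "stable": np.isin(np.arange(len(self.frequencies)),
                              self.stable_set),
        })
        return df.sort_values("frequency", ascending=False,
                              ignore_index=True)

    def summary(self) -> str:
        head = (f"Stable sparse classifier: {self.n_iter} iterations, "
                f"threshold {self.model.threshold:.0%}, "
                f"{len(self.stable_set)} stable feature(s)")
        rows = self.frequency_table()
        rows = rows[rows["stable"]]
        if rows.empty:
            return head + "\n  no stable biomarkers"
        body = "\n".join(f"  {r.feature:<28} {r.frequency:6.2f}"
                         for r in rows.itertuples())
        return head + "\n" + body

    def validate(self, n_iter: int = 500, train_fraction: float = 0.7,
                 seed: int | None = 0,
                 target_sensitivity: float = 0.90) -> "ValidationResult":
        """Run the ROC-distribution validation stage on the stable set."""
        return validate_model(self, n_iter=n_iter,
                              train_fraction=train_fraction, seed=seed,
                              target_sensitivity=target_sensitivity)


@dataclass
class OperatingPoint:
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    target_met: bool = True


@dataclass
class ValidationResult:
    """Resampled out-of-sample ROC performance of the stable model."""

    aucs: np.ndarray
    median_auc: float
    fpr_grid: np.ndarray
    tpr_median: np.ndarray
    tpr_lower: np.ndarray      # pointwise 2.5 %
    tpr_upper: np.ndarray      # pointwise 97.5 %
    pooled_scores: np.ndarray = field(repr=False, default=None)
    pooled_labels: np.ndarray = field(repr=False, default=None)
    stable_features: list[str] = field(default_factory=list)
    no_stable_biomarkers: bool = False

    def operating_point(self, target_sensitivity: float = 0.90
                        ) -> OperatingPoint:
        return operating_point(self, target_sensitivity)

    def summary(self, target_sensitivity: float = 0.90) -> str:
        if self.no_stable_biomarkers:
            return "Validation: no stable biomarkers"
        op = self.operating_point(target_sensitivity)
        return (f"Validation over {len(self.aucs)} resamples: "
                f"median AUC {self.median_auc:.2f} "
                f"[{np.percentile(self.aucs, 2.5):.2f}, "
                f"{np.percentile(self.aucs, 97.5):.2f}]\n"
                f"  at sensitivity >= {target_sensitivity:.0%}: "
                f"sensitivity {op.sensitivity:.1%}, "
                f"specificity {op.specificity:.1%}, "
                f"accuracy {op.accuracy:.1%}")

    def plot_roc(self, ax=None, label: str | None = None):
        """ROC median curve with the pointwise 95 % band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr_grid, self.tpr_median, label=label)
        ax.fill_between(self.fpr_grid, self.tpr_lower, self.tpr_upper,
                        alpha=0.25)
        ax.plot([0, 1], [0, 1], ls=":", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        if label:
            ax.legend()
        return ax


def validate_model(selection: StabilityResult, n_iter: int = 500,
                   train_fraction: float = 0.7, seed: int | None = 0,
                   target_sensitivity: float = 0.90) -> ValidationResult:
    """Stratified 70/30 refit-and-score loop on the stable feature set."""
    model = selection.model
    if len(selection.stable_set) == 0:
        return ValidationResult(aucs=np.array([]), median_auc=np.nan,
                                fpr_grid=np.linspace(0, 1, 101),
                                tpr_median=np.full(101, np.nan),
                                tpr_lower=np.full(101, np.nan),
                                tpr_upper=np.full(101, np.nan),
                                no_stable_biomarkers=True)
    X = model.X[:, selection.stable_set]
    y = model.y01
    rng = np.random.default_rng(seed)
    fpr_grid = np.linspace(0, 1, 101)
    aucs, tprs, scores, labels = [], [], [], []
    for _ in range(n_iter):
        train = _stratified_subsample(y, train_fraction, rng)
        test = np.setdiff1d(np.arange(len(y)), train)
        if len(np.unique(y[test])) < 2:
            continue
        lam, _, _ = cv_select_lambda(X[train], y[train], model.config,
                                     seed=rng)
        fit = elastic_net_fit(X[train], y[train], model.config, lam)
        s = fit.predict(X[test])
        aucs.append(roc_auc_score(y[test], s))
        fpr, tpr, _ = roc_curve(y[test], s)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
        scores.append(s)
        labels.append(y[test])
    aucs = np.asarray(aucs)
    tprs = np.asarray(tprs)
    return ValidationResult(
        aucs=aucs, median_auc=float(np.median(aucs)),
        fpr_grid=fpr_grid,
        tpr_median=np.median(tprs, axis=0),
        tpr_lower=np.percentile(tprs, 2.5, axis=0),
        tpr_upper=np.percentile(tprs, 97.5, axis=0),
        pooled_scores=np.concatenate(scores),
        pooled_labels=np.concatenate(labels),
        stable_features=selection.stable_features)


def operating_point(result: ValidationResult,
                    target_sensitivity: float = 0.90) -> OperatingPoint:
    """Score threshold with the smallest sensitivity >= the target.

    Sensitivity/specificity are computed on the pooled held-out scores of
    all validation resamples; accuracy uses the pooled class prevalences.
    If only a degenerate threshold reaches the target (e.g. constant
    scores), the maximal attainable point is returned with
    ``target_met=False``.
    """
    if result.no_stable_biomarkers or result.pooled_scores is None:
        raise ValueError("no ROC information available")
    s, y = result.pooled_scores, result.pooled_labels
    fpr, tpr, thr = roc_curve(y, s)
    ok = np.flatnonzero(tpr >= target_sensitivity)
    k = ok[np.argmin(tpr[ok])]
    # among thresholds with that sensitivity, take the most specific one
    ties = np.flatnonzero(tpr == tpr[k])
    k = ties[np.argmin(fpr[ties])]
    prev = float(np.mean(y))
    sens, spec = float(tpr[k]), float(1 - fpr[k])
    acc = prev * sens + (1 - prev) * spec
    target_met = bool(spec > 0.0 or sens < 1.0)
    return OperatingPoint(sensitivity=sens, specificity=spec, accuracy=acc,
                          threshold=float(thr[k]), target_met=target_met)
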