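"""Statistical comparisons: permutation two-way ANOVA, rank-based model
comparison with Bonferroni correction, and SVM/LDA baseline classifiers.

The ANOVA handles the repeated-measures design (each subject performs
every walking task) with a restricted permutation scheme: group labels
are permuted between subjects for the GROUP and interaction effects,
task labels within subjects for the TASK effect.  P-values use the
add-one convention p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "AnovaResult",
    "permutation_anova2",
    "ModelComparison",
    "compare_model_aucs",
    "baseline_classifiers",
]


@dataclass
class AnovaResult:
    """Observed F statistics and permutation p-values for both main
    effects and their interaction."""

    f_group: float
    f_task: float
    f_interaction: float
    p_group: float
    p_task: float
    p_interaction: float
    n_permutations: int

    def summary(self) -> str:
        return ("effect          F        p\n"
                f"GROUP     {self.f_group:8.3f} {self.p_group:8.4f}\n"
                f"TASK      {self.f_task:8.3f} {self.p_task:8.4f}\n"
                f"GROUPxTASK{self.f_interaction:8.3f} "
                f"{self.p_interaction:8.4f}")


def _two_way_ss(Y: np.ndarray, gidx: list[np.ndarray]):
    """Sums of squares of the two-way (group x task) layout.

    ``Y`` is subjects x tasks; ``gidx`` lists the subject indices of each
    group.  Task structure is balanced (every subject has every task), so
    the classical proportional-design decomposition applies.
    """
    S, T = Y.shape
    grand = Y.mean()
    sst = ((Y - grand) ** 2).sum()
    task_means = Y.mean(axis=0)
    ss_task = S * ((task_means - grand) ** 2).sum()
    ss_group = 0.0
    ss_cells = 0.0
    for idx in gidx:
        ng = len(idx)
        gm = Y[idx].mean()
        ss_group += T * ng * (gm - grand) ** 2
        cm = Y[idx].mean(axis=0)
        ss_cells += ng * ((cm - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_task
    ss_err = sst - ss_cells
    return ss_group, ss_task, ss_inter, ss_err


def _f_stats(Y, gidx):
    S, T = Y.shape
    a = len(gidx)
    ssg, sst_, ssi, sse = _two_way_ss(Y, gidx)
    dfe = S * T - a * T
    mse = sse / dfe
    if mse <= 0:
        return 0.0, 0.0, 0.0
    return (ssg / (a - 1) / mse, sst_ / (T - 1) / mse,
            ssi / ((a - 1) * (T - 1)) / mse)


def permutation_anova2(values, groups, tasks, n_perm: int = 999,
                       seed: int | None = 0) -> AnovaResult:
    """Permutation two-way ANOVA with GROUP and TASK main effects.

    Parameters
    ----------
    values : long-format array/Series of one gait feature
    groups : group label per observation (constant within subject)
    tasks : task label per observation
        The design must be balanced: each subject appears once per task.
        Subjects are identified implicitly by position: observations are
        reshaped to subjects x tasks via a (group-stable) pivot, so pass
        a DataFrame-like triple where each subject's rows carry identical
        group labels.  Alternatively pass ``values`` as a DataFrame
        indexed by subject with one column per task and ``groups`` per
        subject; ``tasks`` is then ignored.
    """
    if isinstance(values, pd.DataFrame):
        Y = values.to_numpy(dtype=float)
        g = np.asarray(groups)
    else:
        df = pd.DataFrame({"v": np.asarray(values, dtype=float),
                           "g": np.asarray(groups),
                           "t": np.asarray(tasks)})
        df["subject"] = df.groupby("t").cumcount()
        wide = df.pivot(index="subject", columns="t", values="v")
        if wide.isna().any().any():
            raise ValueError("unbalanced design: every subject needs "
                             "every task")
        Y = wide.to_numpy(dtype=float)
        g = df.drop_duplicates("subject").sort_values("subject")[
            "g"].to_numpy()
    S, T = Y.shape
    if T < 2:
        raise ValueError("need at least two tasks")
    labels, counts = np.unique(g, return_counts=True)
    if counts.min() == 0 or len(labels) < 2:
        raise ValueError("empty group cell")
    if np.allclose(Y, Y.flat[0]):
        return AnovaResult(0.0, 0.0, 0.0, 1.0, 1.0, 1.0, n_perm)
    gidx = [np.flatnonzero(g == lab) for lab in labels]
    f_g, f_t, f_i = _f_stats(Y, gidx)
    rng = np.random.default_rng(seed)

    a = len(gidx)
    dfe = S * T - a * T
    sizes = np.array([len(i) for i in gidx])
    bounds = np.concatenate(([0], np.cumsum(sizes)))
    # GROUP and interaction: permute which subjects belong to which group
    perms = np.array([rng.permutation(S) for _ in range(n_perm)])
    # interaction nulls are built on residuals after both main effects
    resid = Y.copy()
    for idx in gidx:
        resid[idx] -= Y[idx].mean()
    resid -= Y.mean(axis=0) - Y.mean()
    _, _, f_i_obs = _f_stats(resid, gidx)

    def _batch_group_stats(M: np.ndarray):
        """(ss_group, ss_cells) per permutation via sum-of-squares
        computational formulas; returns arrays of length n_perm."""
        C = M.sum() ** 2 / (S * T)
        rs = M.sum(axis=1)
        ssg = -C
        cells = -C
        for k in range(a):
            idx = perms[:, bounds[k]:bounds[k + 1]]
            gs = rs[idx].sum(axis=1)
            ssg = ssg + gs ** 2 / (T * sizes[k])
            cs = M[idx].sum(axis=1)            # (n_perm, T)
            cells = cells + (cs ** 2).sum(axis=1) / sizes[k]
        return ssg, cells

    tot_y = ((Y - Y.mean()) ** 2).sum()
    ssg_p, cells_p = _batch_group_stats(Y)
    mse_p = (tot_y - cells_p) / dfe
    count_g = int(np.sum(ssg_p / (a - 1) / mse_p >= f_g - 1e-12))

    tot_r = ((resid - resid.mean()) ** 2).sum()
    Cr = resid.sum() ** 2 / (S * T)
    ssg_r, cells_r = _batch_group_stats(resid)
    sst_r = (resid.sum(axis=0) ** 2).sum() / S - Cr
    ssi_r = cells_r - ssg_r - sst_r
    mse_r = (tot_r - cells_r) / dfe
    f_i_perm = ssi_r / ((a - 1) * (T - 1)) / mse_r
    count_i = int(np.sum(f_i_perm >= f_i_obs - 1e-12))

    # TASK: permute task labels within each subject
    cols = np.broadcast_to(np.arange(T), (n_perm, S, T))
    pc = rng.permuted(np.ascontiguousarray(cols), axis=2)
    Yp = np.take_along_axis(np.broadcast_to(Y, (n_perm, S, T)), pc, axis=2)
    C = Y.sum() ** 2 / (S * T)
    sst_p = (Yp.sum(axis=1) ** 2).sum(axis=1) / S - C
    cells_t = -C
    for k in range(a):
        cs = Yp[:, gidx[k], :].sum(axis=1)
        cells_t = cells_t + (cs ** 2).sum(axis=1) / sizes[k]
    mse_t = (tot_y - cells_t) / dfe
    count_t = int(np.sum(sst_p / (T - 1) / mse_t >= f_t - 1e-12))
    return AnovaResult(
        f_group=f_g, f_task=f_t, f_interaction=f_i,
        p_group=(1 + count_g) / (1 + n_perm),
        p_task=(1 + count_t) / (1 + n_perm),
        p_interaction=(1 + count_i) / (1 + n_perm),
        n_permutations=n_perm)


@dataclass
class ModelComparison:
    """Mean AUC ranks per model with Bonferroni pairwise comparisons."""

    table: pd.DataFrame       # model, mean_rank, ci_low, ci_high,
    #                           rank_diff, p_corrected, significant
    reference: str
    alpha: float
    n_comparisons: int

    def summary(self) -> str:
        lines = [f"AUC mean-rank comparison vs {self.reference} "
                 f"(Bonferroni alpha={self.alpha:g}, "
                 f"m={self.n_comparisons})"]
        for r in self.table.itertuples():
            mark = "*" if r.significant else " "
            lines.append(f"  {r.model:<18} rank {r.mean_rank:9.1f} "
                         f"[{r.ci_low:9.1f}, {r.ci_high:9.1f}] "
                         f"p={r.p_corrected:.4f}{mark}")
        return "\n".join(lines)


def compare_model_aucs(auc_samples: dict[str, np.ndarray],
                       reference: str, alpha: float = 0.05
                       ) -> ModelComparison:
    """Rank-based pairwise comparison of per-model AUC distributions.

    All AUC values are pooled and ranked; each model's mean rank is
    compared with the reference model's using the normal approximation
    for rank-sum differences, with Bonferroni correction over the
    non-reference models.  Simultaneous confidence intervals use the
    Bonferroni-adjusted normal quantile.
    """
    models = list(auc_samples)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    if reference not in auc_samples:
        raise KeyError(f"reference model {reference!r} not in samples")
    sizes = [len(v) for v in auc_samples.values()]
    if len(set(sizes)) != 1:
        raise ValueError("AUC samples must have equal length")
    pooled = np.concatenate([np.asarray(auc_samples[m], float)
                             for m in models])
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    var_unit = N * (N + 1) / 12.0
    m_comp = len(models) - 1
    z_ci = stats.norm.ppf(1 - alpha / (2 * m_comp))
    rows = []
    splits = np.cumsum(sizes)[:-1]
    per_model = dict(zip(models, np.split(ranks, splits)))
    ref_rank = per_model[reference].mean()
    n_ref = len(per_model[reference])
    for m in models:
        r = per_model[m]
        mean_rank = r.mean()
        se_mean = np.sqrt(var_unit / len(r))
        if m == reference:
            p_corr, sig = 1.0, False
            diff = 0.0
        else:
            diff = mean_rank - ref_rank
            se = np.sqrt(var_unit * (1 / len(r) + 1 / n_ref))
            p = 2 * stats.norm.sf(abs(diff) / se)
            p_corr = min(p * m_comp, 1.0)
            sig = p_corr < alpha
        rows.append(dict(model=m, mean_rank=mean_rank,
                         ci_low=mean_rank - z_ci * se_mean,
                         ci_high=mean_rank + z_ci * se_mean,
                         rank_diff=diff, p_corrected=p_corr,
                         significant=sig))
    return ModelComparison(table=pd.DataFrame(rows), reference=reference,
                           alpha=alpha, n_comparisons=m_comp)


def baseline_classifiers(X, y, folds: int = 10, reps: int = 500,
                         seed: int | None = 0) -> pd.DataFrame:
    """Repeated stratified k-fold AUC for SVM (RBF) and shrinkage LDA.

    Both classifiers share identical fold assignments within each
    repetition; standardization is fitted inside every training fold.
    Returns a DataFrame indexed by classifier with columns
    ``auc_mean``/``auc_sd`` (over repetitions) and the per-repetition
    samples in ``.attrs['aucs']``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y01 = (y == classes[1]).astype(int)
    if np.bincount(y01).min() < folds:
        raise ValueError("minority class smaller than the fold count")
    rng = np.random.default_rng(seed)
    makers = {
        "SVM": lambda: make_pipeline(StandardScaler(), SVC()),
        "LDA": lambda: make_pipeline(
            StandardScaler(),
            LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")),
    }
    aucs = {name: np.empty(reps) for name in makers}
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        scores = {name: np.empty(len(y01)) for name in makers}
        for train, test in skf.split(X, y01):
            for name, make in makers.items():
                clf = make().fit(X[train], y01[train])
                scores[name][test] = clf.decision_function(X[test])
        for name in makers:
            aucs[name][rep] = roc_auc_score(y01, scores[name])
    out = pd.DataFrame({
        "auc_mean": {n: a.mean() for n, a in aucs.items()},
        "auc_sd": {n: a.std(ddof=1) for n, a in aucs.items()},
    })
    out.index.name = "classifier"
    out.attrs["aucs"] = aucs
    return out
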