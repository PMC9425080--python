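"""Cognitive index: normative regression, Mahalanobis MDCog, and the
k-means group definition."""

import numpy as np
import pandas as pd
import pytest

from stablegait.cogindex import CognitiveNormativeModel, NormativeResults, \
    cluster_groups, compute_mdcog, fit_normative_model
from stablegait.synth import CohortSpec, generate_cognitive_scores, \
    generate_cohort, generate_normative_scores
from stablegait.synth.cognitive import MEASURE_DEFS, MEASURES


def _plain_results(k=12):
    """Identity-covariance normative model with zero adjustment, on
    neutral measure names (no orientation flips)."""
    model = CognitiveNormativeModel.__new__(CognitiveNormativeModel)
    model.measures = [f"m{i}" for i in range(k)]
    model.lower_better = tuple(model.measures)  # no sign flips
    model.scores = None
    return NormativeResults(model=model, coef=np.zeros((k, 3)),
                            resid_cov=np.eye(k), n_obs=100)


class TestNormativeFit:
    def test_recovers_generating_coefficients(self):
        """On a large normative sample the fitted age/education slopes
        match the generator's (deficit-scale slopes mapped through each
        measure's sign and unit scale)."""
        df = generate_normative_scores(5000, seed=0)
        res = fit_normative_model(df)
        n = len(df)
        for j, (name, worse, _, scale, ba, be) in enumerate(MEASURE_DEFS):
            # generator: raw = base +/- scale * deficit; fit orients all
            # measures to the deficit scale, so slopes are scale * beta
            resid_sd = np.sqrt(res.resid_cov[j, j])
            se = resid_sd / (df["age"].std() * np.sqrt(n))
            assert abs(res.coef[j, 1] - scale * ba) < 3 * se
            se_e = resid_sd / (df["education"].std() * np.sqrt(n))
            assert abs(res.coef[j, 2] - scale * be) < 3 * se_e

    def test_identity_residual_covariance_recovered(self):
        """Frobenius error of the correlation estimate shrinks with n."""
        errs = []
        for n in (300, 3000):
            df = generate_normative_scores(n, seed=1)
            res = fit_normative_model(df)
            scales = np.array([m[3] for m in MEASURE_DEFS])
            corr = res.resid_cov / np.outer(scales, scales)
            from stablegait.synth.cognitive import \
                default_residual_correlation
            errs.append(np.linalg.norm(corr - default_residual_correlation()))
        assert errs[1] < errs[0] < 2.0

    def test_constant_education_is_singular(self):
        df = generate_normative_scores(100, seed=2)
        df["education"] = 12.0
        with pytest.raises(ValueError, match="singular"):
            fit_normative_model(df)

    def test_requires_minimum_sample(self):
        df = generate_normative_scores(10, seed=3)
        with pytest.raises(ValueError):
            fit_normative_model(df)

    def test_json_round_trip(self, tmp_path):
        df = generate_normative_scores(200, seed=4)
        res = fit_normative_model(df)
        path = tmp_path / "norm.json"
        res.to_json(path)
        back = NormativeResults.from_json(path)
        np.testing.assert_allclose(back.coef, res.coef)
        np.testing.assert_allclose(back.resid_cov, res.resid_cov)
        probe = generate_normative_scores(20, seed=5)
        pd.testing.assert_series_equal(back.mahalanobis(probe),
                                       res.mahalanobis(probe))


class TestMdcog:
    def test_zero_residual_gives_zero(self):
        res = _plain_results()
        row = pd.DataFrame([{**{f"m{i}": 0.0 for i in range(12)},
                             "age": 70.0, "education": 12.0}])
        assert compute_mdcog(row, res).iloc[0] == pytest.approx(0.0)

    def test_identity_covariance_is_euclidean(self):
        res = _plain_results()
        vals = {f"m{i}": 0.0 for i in range(12)}
        vals["m0"], vals["m1"] = 3.0, 4.0
        row = pd.DataFrame([{**vals, "age": 70.0, "education": 12.0}])
        assert compute_mdcog(row, res).iloc[0] == pytest.approx(5.0)

    def test_affine_invariance_under_measure_mixing(self):
        """Applying an invertible linear map to the measures (and
        refitting) leaves the Mahalanobis index unchanged."""
        rng = np.random.default_rng(6)
        norm = generate_normative_scores(2000, seed=7)
        probe = generate_normative_scores(30, seed=8)
        base = fit_normative_model(norm).mahalanobis(probe)
        T = rng.normal(size=(12, 12)) + 4 * np.eye(12)
        for df in (norm, probe):
            df[MEASURES] = df[MEASURES].to_numpy() @ T.T
        # disable orientation flips: they are sign conventions that the
        # mixing destroys, and the distance is invariant to them anyway
        mixed = CognitiveNormativeModel(norm, measures=MEASURES,
                                        lower_better=MEASURES).fit()
        after = mixed.mahalanobis(probe)
        np.testing.assert_allclose(after, base, rtol=1e-6)

    def test_missing_values_rejected(self):
        res = _plain_results()
        row = pd.DataFrame([{**{f"m{i}": 0.0 for i in range(12)},
                             "age": 70.0, "education": 12.0}])
        row.loc[0, "m3"] = np.nan
        with pytest.raises(ValueError):
            compute_mdcog(row, res)

    def test_monotone_in_each_whitened_coordinate(self):
        res = _plain_results()
        base = {f"m{i}": 0.5 for i in range(12)}
        prev = -1.0
        for v in (0.5, 1.5, 3.0):
            row = pd.DataFrame([{**base, "m4": v, "age": 70.0,
                                 "education": 12.0}])
            d = compute_mdcog(row, res).iloc[0]
            assert d > prev
            prev = d


class TestClustering:
    def test_two_obvious_clusters_split_correctly(self):
        md = pd.Series([2.0, 2.1, 9.0, 9.5], index=list("abcd"))
        ages = pd.Series([70, 75, 72, 80.0], index=list("abcd"))
        gl = cluster_groups(md, ages, repeats=50, seed=0)
        assert list(gl.labels) == ["HE", "HE", "MCI-E", "MCI-E"]
        assert 2.1 < gl.boundary < 9.0

    def test_young_healthy_subject_labelled_ya(self):
        md = pd.Series([2.0, 2.1, 2.2, 9.0, 9.5])
        ages = pd.Series([30, 70, 75, 72, 80.0])
        gl = cluster_groups(md, ages, repeats=50, seed=0)
        assert gl.labels.iloc[0] == "YA"

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            cluster_groups(pd.Series([3.0, 3.0, 3.0]),
                           pd.Series([70, 71, 72.0]), repeats=10, seed=0)

    def test_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(9)
        md = pd.Series(np.r_[rng.normal(3, 1, 40), rng.normal(9, 1.5, 15)],
                       index=[f"s{i}" for i in range(55)])
        ages = pd.Series(rng.uniform(60, 85, 55), index=md.index)
        a = cluster_groups(md, ages, repeats=100, seed=3)
        b = cluster_groups(md, ages, repeats=100, seed=3)
        pd.testing.assert_series_equal(a.labels, b.labels)
        perm = rng.permutation(55)
        c = cluster_groups(md.iloc[perm], ages.iloc[perm], repeats=100,
                           seed=3)
        pd.testing.assert_series_equal(c.labels.sort_index(),
                                       a.labels.sort_index())

    def test_matches_reference_kmeans(self):
        """The vectorized 1-D Lloyd restarts find the same partition and
        inertia as scikit-learn's k-means on a bimodal sample."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(10)
        x = np.r_[rng.normal(3, 1, 60), rng.normal(9, 1.5, 25)]
        gl = cluster_groups(pd.Series(x), pd.Series(np.full(85, 70.0)),
                            repeats=100, seed=0)
        km = KMeans(n_clusters=2, n_init=20, random_state=0).fit(
            x.reshape(-1, 1))
        ours = gl.labels == "MCI-E"
        theirs = km.labels_ == km.cluster_centers_.ravel().argmax()
        assert np.array_equal(ours.to_numpy(), theirs)
        assert gl.inertia == pytest.approx(km.inertia_, rel=1e-9)


class TestCohortLevelBehaviour:
    def test_group_mdcog_means_match_targets(self):
        """Across replicate synthetic cohorts the recovered MDCog group
        means sit within Monte-Carlo error of the design targets."""
        targets = {"YA": (2.91, 0.97, 40), "HE": (3.81, 1.08, 62),
                   "MCI-E": (9.30, 1.65, 23)}
        n_rep = 12
        means = {g: [] for g in targets}
        for rep in range(n_rep):
            cohort = generate_cohort(CohortSpec(seed=rep))
            scores = generate_cognitive_scores(cohort, seed=100 + rep)
            norm = generate_normative_scores(400, seed=200 + rep)
            res = fit_normative_model(norm)
            md = compute_mdcog(scores, res)
            groups = pd.Series({s.id: s.group for s in cohort})
            for g in targets:
                means[g].append(md[groups == g].mean())
        for g, (mu, sd, n) in targets.items():
            se = sd / np.sqrt(n * n_rep)
            # allow 3 MC standard errors plus covariance-estimation bias
            assert abs(np.mean(means[g]) - mu) < 3 * se + 0.30

    def test_clustering_recovers_groups_and_boundary(self):
        """Replicate cohorts: < 10 % misassignment on average and the
        healthy/impaired decision boundary near six."""
        mis, bounds = [], []
        for rep in range(10):
            cohort = generate_cohort(CohortSpec(seed=50 + rep))
            scores = generate_cognitive_scores(cohort, seed=300 + rep)
            norm = generate_normative_scores(400, seed=400 + rep)
            md = compute_mdcog(scores, fit_normative_model(norm))
            truth = pd.Series({s.id: s.group for s in cohort})[md.index]
            ages = pd.Series({s.id: s.age for s in cohort})[md.index]
            gl = cluster_groups(md, ages, repeats=200, seed=rep)
            mis.append(np.mean(gl.labels != truth))
            bounds.append(gl.boundary)
        assert np.mean(mis) < 0.10
        assert 5.0 < np.median(bounds) < 7.5
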