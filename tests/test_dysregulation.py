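import numpy as np
import pandas as pd
import pytest

from physdys import dysregulation as dy


def _table(x, sex=None, age=None, **extra):
    """Assemble a subject table from a biomarker matrix."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    df = pd.DataFrame(x, columns=[f"b{j}" for j in range(p)])
    df["sex"] = 0 if sex is None else sex
    df["age_baseline"] = 50.0 if age is None else age
    for k, v in extra.items():
        df[k] = v
    return df


def _fit_single_stratum(x):
    df = _table(x)
    names = [c for c in df.columns if c.startswith("b")]
    return df, names, dy.fit_reference(df, names)


def brute_force_dm(x, centroid, cov):
    """Independent oracle: explicit inverse, double loop over subjects."""
    inv = np.linalg.inv(cov)
    out = np.empty(len(x))
    for i in range(len(x)):
        d = x[i] - centroid
        out[i] = np.sqrt(d @ inv @ d)
    return out


class TestComputeDm:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=(50, 5)) @ rng.normal(size=(5, 5))
            df, names, model = _fit_single_stratum(x)
            got = dy.compute_dm(df, model).to_numpy()
            s = model.strata[0]
            want = brute_force_dm(x, s.centroid, s.covariance)
            assert np.max(np.abs(got - want)) < 1e-8

    def test_centroid_scores_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        df, names, model = _fit_single_stratum(x)
        probe = _table(model.strata[0].centroid[None, :])
        assert dy.compute_dm(probe, model)[0] == pytest.approx(0.0, abs=1e-10)

    def test_euclidean_case(self):
        # identity covariance, deviation (3, 4) -> distance 5
        model = dy.ReferenceModel(biomarker_names=["b0", "b1"])
        from scipy.linalg import cho_factor
        cov = np.eye(2)
        model.strata[0] = dy._Stratum(centroid=np.zeros(2), covariance=cov,
                                      n_ref=100, cho_factor=cho_factor(cov, lower=True))
        probe = _table([[3.0, 4.0]])
        assert dy.compute_dm(probe, model)[0] == pytest.approx(5.0, abs=1e-12)

    def test_correlated_2x2_closed_form(self):
        # Sigma = [[1, .5], [.5, 1]], dev (1,1): d'S^-1 d = 4/3
        from scipy.linalg import cho_factor
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        model = dy.ReferenceModel(biomarker_names=["b0", "b1"])
        model.strata[0] = dy._Stratum(centroid=np.zeros(2), covariance=cov,
                                      n_ref=100, cho_factor=cho_factor(cov, lower=True))
        probe = _table([[1.0, 1.0]])
        assert dy.compute_dm(probe, model)[0] == pytest.approx(np.sqrt(4 / 3), abs=1e-12)

    @pytest.mark.parametrize("p", [1, 5, 19])
    def test_self_scoring_identity(self, p):
        # mean of squared distance over the fit sample is p*(n-1)/n exactly
        rng = np.random.default_rng(p)
        n = 200
        x = rng.normal(size=(n, p))
        df, names, model = _fit_single_stratum(x)
        dm = dy.compute_dm(df, model)
        assert np.mean(dm**2) == pytest.approx(p * (n - 1) / n, abs=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(80, 4))
        a = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        df1, _, m1 = _fit_single_stratum(x)
        df2, _, m2 = _fit_single_stratum(x @ a)
        d1 = dy.compute_dm(df1, m1).to_numpy()
        d2 = dy.compute_dm(df2, m2).to_numpy()
        assert np.max(np.abs(d1 - d2)) < 1e-8

    def test_univariate_reduces_to_z_score(self):
        rng = np.random.default_rng(4)
        x = rng.normal(2.0, 3.0, size=(100, 1))
        df, _, model = _fit_single_stratum(x)
        s = model.strata[0]
        want = np.abs(x[:, 0] - s.centroid[0]) / np.sqrt(s.covariance[0, 0])
        assert np.allclose(dy.compute_dm(df, model), want, atol=1e-10)

    def test_sex_stratified_scoring(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(5, 1, (60, 2))])
        sex = np.repeat([0, 1], 60)
        df = _table(x, sex=sex)
        model = dy.fit_reference(df, ["b0", "b1"])
        dm = dy.compute_dm(df, model)
        # each sex scored against its own centroid -> comparable magnitudes
        assert abs(dm[sex == 0].mean() - dm[sex == 1].mean()) < 0.5

    def test_missing_biomarker_raises(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(40, 2))
        df, _, model = _fit_single_stratum(x)
        probe = _table([[1.0, np.nan]])
        with pytest.raises(ValueError, match="missing"):
            dy.compute_dm(probe, model)

    def test_unknown_stratum_raises(self):
        rng = np.random.default_rng(7)
        df, _, model = _fit_single_stratum(rng.normal(size=(40, 2)))
        probe = _table([[0.0, 0.0]], sex=2)
        with pytest.raises(KeyError):
            dy.compute_dm(probe, model)


class TestFitReference:
    def test_identical_rows_singular(self):
        x = np.ones((30, 3))
        x += np.arange(30)[:, None]  # perfectly collinear columns
        df = _table(x)
        with pytest.raises(dy.SingularCovarianceError, match="collinear"):
            dy.fit_reference(df, ["b0", "b1", "b2"])

    def test_univariate_covariance_n_minus_1(self):
        x = np.array([[1.0], [2.0], [4.0], [8.0], [3.0], [5.0], [9.0],
                      [2.5], [6.0], [7.0], [1.5], [0.5]])
        df, _, model = _fit_single_stratum(x)
        assert model.strata[0].covariance[0, 0] == pytest.approx(
            np.var(x, ddof=1), abs=1e-12)

    def test_too_small_stratum_raises(self):
        rng = np.random.default_rng(8)
        df = _table(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError, match="too small"):
            dy.fit_reference(df, [f"b{j}" for j in range(5)])

    def test_centroid_recovery_clt(self):
        rng = np.random.default_rng(9)
        mu = np.array([1.0, -2.0, 0.5])
        x = rng.multivariate_normal(mu, np.diag([1.0, 4.0, 0.25]), size=2000)
        df, _, model = _fit_single_stratum(x)
        se = np.sqrt(np.diag(model.strata[0].covariance) / 2000)
        assert np.all(np.abs(model.strata[0].centroid - mu) < 3 * se)


class TestSelectReference:
    def test_strict_age_cutoff(self):
        df = _table(np.zeros((3, 1)), age=np.array([55.0, 60.0, 65.0]))
        out = dy.select_reference(df, ["b0"], age_cutoff=60.0)
        assert list(out.age_baseline) == [55.0]

    def test_healthy_only_noop_without_disease(self):
        df = _table(np.zeros((5, 1)), age=50.0, prevalent_cancer=0,
                    prevalent_cvd=0, prevalent_diabetes=0, prevalent_ad=0)
        a = dy.select_reference(df, ["b0"], healthy_only=True)
        b = dy.select_reference(df, ["b0"], healthy_only=False)
        pd.testing.assert_frame_equal(a, b)

    def test_healthy_only_drops_prevalent_disease(self):
        df = _table(np.zeros((4, 1)), age=50.0,
                    prevalent_cancer=[0, 1, 0, 0], prevalent_cvd=0,
                    prevalent_diabetes=[0, 0, 1, 0], prevalent_ad=0)
        out = dy.select_reference(df, ["b0"], healthy_only=True)
        assert list(out.index) == [0, 3]

    def test_cutoff_monotone_superset(self, cohort_table):
        names = ["albumin", "hba1c"]
        s60 = dy.select_reference(cohort_table, names, age_cutoff=60.0)
        s70 = dy.select_reference(cohort_table, names, age_cutoff=70.0)
        assert set(s60.index) <= set(s70.index)
        assert len(s70) > len(s60)

    def test_exclude_spouses(self):
        df = _table(np.zeros((4, 1)), age=50.0, spouse=[0, 1, 0, 1])
        out = dy.select_reference(df, ["b0"], exclude_spouses=True)
        assert (out.spouse == 0).all()


@pytest.fixture(scope="module")
def dm_raw():
    rng = np.random.default_rng(10)
    return pd.Series(rng.chisquare(10, 500)**0.5)


class TestTransformDm:
    def test_raw_mode_is_identity(self, dm_raw):
        out, spec = dy.transform_dm(dm_raw, mode="raw")
        assert spec is None
        pd.testing.assert_series_equal(out, dm_raw)

    def test_monotone(self, dm_raw):
        out, _ = dy.transform_dm(dm_raw)
        assert dm_raw.corr(out, method="spearman") == pytest.approx(1.0)

    def test_quartile_partition_invariant(self, dm_raw):
        out, _ = dy.transform_dm(dm_raw)
        q_raw = dy.assign_quartiles(dm_raw)
        q_t = dy.assign_quartiles(out)
        assert (q_raw == q_t).all()


class TestQuartiles:
    def test_eight_distinct_values(self):
        v = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8])
        q = dy.assign_quartiles(v)
        assert q.value_counts().eq(2).all()

    def test_by_group_cutpoints_are_stratified(self):
        v = pd.Series(np.r_[np.arange(16.0), np.arange(16.0) + 100])
        sex = pd.Series([0] * 16 + [1] * 16)
        q = dy.assign_quartiles(v, by=sex)
        # each sex has its own quartiles despite the offset
        assert q[sex == 0].value_counts().eq(4).all()
        assert q[sex == 1].value_counts().eq(4).all()

    def test_tie_goes_to_lower_bin(self):
        v = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8])
        cuts = np.quantile(v, [0.25, 0.5, 0.75])
        q = dy.assign_quartiles(pd.Series(np.r_[v, cuts[0]]),
                                defining_mask=pd.Series([True] * 8 + [False]))
        assert q.iloc[-1] == "Q1"

    def test_degenerate_values_raise(self):
        with pytest.raises(ValueError, match="degenerate|fewer"):
            dy.assign_quartiles(pd.Series(np.ones(20)))

    def test_conditioning_mask(self):
        v = pd.Series(np.arange(16.0))
        survived = pd.Series([False] * 8 + [True] * 8)
        q = dy.assign_quartiles(v, defining_mask=survived)
        # cut points from the upper half only -> lower half all Q1
        assert (q[:8] == "Q1").all()


def _controlled_corr_table(corrs, n=400):
    """Biomarkers with exact sample correlations to age (Gram-Schmidt)."""
    rng = np.random.default_rng(13)
    age = np.linspace(30, 90, n)
    a = (age - age.mean()) / np.linalg.norm(age - age.mean())
    cols = {}
    for j, r in enumerate(corrs):
        e = rng.normal(size=n)
        e -= e.mean()
        e -= (e @ a) * a
        e /= np.linalg.norm(e)
        cols[f"b{j}"] = r * a + np.sqrt(1 - r**2) * e
    df = pd.DataFrame(cols)
    df["age_baseline"] = age
    return df


class TestBiomarkerSubsets:
    def test_age_corr_threshold(self):
        df = _controlled_corr_table([0.02, 0.10, -0.30])
        keep = dy.select_biomarker_subset(df, ["b0", "b1", "b2"],
                                          "age_corr_threshold", threshold=0.05)
        assert keep == ["b1", "b2"]

    def test_sign_split(self):
        df = _controlled_corr_table([0.3, -0.2, 0.1])
        pos = dy.select_biomarker_subset(df, ["b0", "b1", "b2"], "positive_age_corr")
        neg = dy.select_biomarker_subset(df, ["b0", "b1", "b2"], "negative_age_corr")
        assert pos == ["b0", "b2"] and neg == ["b1"]

    def test_decorrelate_duplicate_column(self):
        df = _controlled_corr_table([0.1, 0.2])
        df["b2"] = df["b0"]  # perfect copy
        keep = dy.select_biomarker_subset(df, ["b0", "b1", "b2"], "decorrelate")
        assert keep in (["b0", "b1"], ["b1", "b2"])
        assert len(keep) == 2

    def test_unknown_rule_raises(self):
        df = _controlled_corr_table([0.1])
        with pytest.raises(ValueError):
            dy.select_biomarker_subset(df, ["b0"], "nope")

    def test_threshold_bounds(self):
        df = _controlled_corr_table([0.1])
        with pytest.raises(ValueError):
            dy.select_biomarker_subset(df, ["b0"], "age_corr_threshold",
                                       threshold=1.5)
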