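import numpy as np
import pytest
from scipy import stats

from eaafinger import (
    EAA_PANEL,
    ClassSpec,
    LDAResults,
    LinearDiscriminant,
    TrainingSimConfig,
    calibrate_interlab,
    confidence_ellipse,
    fingerprint_table,
    lda_fit,
    loocv,
    mean_center,
    simulate_training,
)
from eaafinger.exceptions import (
    CoverageError,
    NumericalError,
    SampleSizeError,
    ValidationError,
)


class TestMeanCenter:
    def test_arithmetic(self):
        np.testing.assert_allclose(
            mean_center([-10.0, -20.0, -30.0]), [10.0, 0.0, -10.0]
        )

    def test_constant_vector_maps_to_zero(self):
        np.testing.assert_allclose(mean_center([3.0] * 6), np.zeros(6))

    def test_translation_invariance(self, rng):
        x = rng.normal(size=6)
        np.testing.assert_allclose(mean_center(x), mean_center(x + 5.0), atol=1e-12)

    def test_mapping_input_requires_full_panel(self):
        with pytest.raises(CoverageError):
            mean_center({"Ile": -20.0})


class TestCalibration:
    def test_identity_when_reference_agrees(self, small_table):
        ref = {aa: -20.0 for aa in EAA_PANEL}
        out = calibrate_interlab(small_table, ref, ref)
        np.testing.assert_allclose(
            out.data["delta13c"], small_table.data["delta13c"]
        )

    def test_single_eaa_bias_shifts_only_that_eaa(self, small_table):
        measured = {aa: -20.0 for aa in EAA_PANEL}
        known = dict(measured)
        measured["Thr"] = -19.6  # lab reads Thr 0.4 too high
        out = calibrate_interlab(small_table, measured, known)
        diff = out.data["delta13c"] - small_table.data["delta13c"]
        is_thr = small_table.data["amino_acid"] == "Thr"
        np.testing.assert_allclose(diff[is_thr], -0.4)
        np.testing.assert_allclose(diff[~is_thr], 0.0)

    def test_panel_mismatch_rejected(self, small_table):
        with pytest.raises(CoverageError):
            calibrate_interlab(small_table, {"Ile": 0.0}, {"Leu": 0.0})

    def test_constant_correction_invisible_to_fingerprints(self, h0_experiment):
        measured = {aa: -20.0 for aa in EAA_PANEL}
        known = {aa: -19.0 for aa in EAA_PANEL}  # +1 on every EAA
        consumers = h0_experiment.subset(group=["GF", "CVZ"])
        fp1 = fingerprint_table(consumers)
        fp2 = fingerprint_table(calibrate_interlab(consumers, measured, known))
        np.testing.assert_allclose(fp1.to_numpy(), fp2.to_numpy(), atol=1e-12)


class TestLdaFit:
    def test_two_class_direction_matches_analytic(self, rng):
        """The single discriminant aligns with Sigma^-1 (mu1 - mu2)."""
        n = 200
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        L = np.linalg.cholesky(cov)
        Xa = rng.standard_normal((n, 2)) @ L.T
        Xb = rng.standard_normal((n, 2)) @ L.T + np.array([4.0, 0.0])
        X = np.vstack([Xa, Xb])
        y = ["a"] * n + ["b"] * n
        res = LinearDiscriminant(X, y).fit()
        w = res.scaling[:, 0]
        analytic = np.linalg.solve(
            res.within_cov, res.class_means[1] - res.class_means[0]
        )
        cos = abs(w @ analytic) / np.linalg.norm(w) / np.linalg.norm(analytic)
        assert cos > 0.999999

    def test_projected_training_has_identity_within_covariance(self, default_training):
        res = lda_fit(default_training)
        Z = res.transform(default_training.X)
        W = np.zeros((res.n_components, res.n_components))
        for c in res.classes:
            sub = Z[default_training.labels == c]
            R = sub - sub.mean(axis=0)
            W += R.T @ R
        W /= len(default_training) - len(res.classes)
        np.testing.assert_allclose(W, np.eye(res.n_components), atol=1e-8)

    def test_collinear_class_means_give_one_informative_discriminant(self, rng):
        mus = {"a": 0.0, "b": 2.0, "c": 4.0}  # collinear along axis 0
        X, y = [], []
        for lab, m in mus.items():
            X.append(rng.standard_normal((30, 3)) + np.array([m, 0.0, 0.0]))
            y += [lab] * 30
        res = LinearDiscriminant(np.vstack(X), y).fit()
        assert res.separation[1] < 0.05 * res.separation[0]

    def test_class_mean_projects_to_centroid(self, default_training):
        res = lda_fit(default_training)
        for i, c in enumerate(res.classes):
            z = res.transform(res.class_means[i])
            np.testing.assert_allclose(z[0], res.class_scores[i], atol=1e-10)

    def test_label_swap_preserves_subspace(self, default_training):
        res1 = lda_fit(default_training)
        swapped = np.where(
            default_training.labels == "bacteria", "plants",
            np.where(default_training.labels == "plants", "bacteria",
                     default_training.labels),
        )
        res2 = LinearDiscriminant(default_training.X, swapped).fit()
        # same span: projection matrices agree
        def proj(S):
            Q, _ = np.linalg.qr(S)
            return Q @ Q.T
        np.testing.assert_allclose(
            proj(res1.scaling), proj(res2.scaling), atol=1e-8
        )

    def test_class_below_two_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(SampleSizeError):
            LinearDiscriminant(X, ["a", "a", "b"])

    def test_sign_convention_largest_loading_positive(self, default_training):
        res = lda_fit(default_training)
        for j in range(res.n_components):
            i = np.argmax(np.abs(res.scaling[:, j]))
            assert res.scaling[i, j] > 0

    def test_matches_sklearn_transform_subspace(self, default_training):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        # svd solver tolerates the zero-sum (collinear) fingerprint panel
        sk = sklearn.LinearDiscriminantAnalysis(solver="svd", tol=1e-8)
        sk.fit(default_training.X, default_training.labels)
        res = lda_fit(default_training)
        ours, theirs = res.classify(default_training.X)[0], sk.predict(default_training.X)
        assert (ours == theirs).mean() > 0.95


class TestClassification:
    def test_posteriors_sum_to_one(self, default_training, rng):
        res = lda_fit(default_training)
        X = rng.normal(size=(20, 6))
        X -= X.mean(axis=1, keepdims=True)
        _, post = res.classify(X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_class_centroid_classified_to_class(self, default_training):
        res = lda_fit(default_training)
        labels, post = res.classify(res.class_means)
        assert list(labels) == res.classes

    def test_equidistant_tie_broken_by_label_order(self):
        X = np.array([[-1.0, 0.0], [-1.2, 0.1], [1.0, 0.0], [1.2, -0.1],
                      [-1.1, -0.05], [1.1, 0.05]])
        y = ["a", "a", "b", "b", "a", "b"]
        res = LinearDiscriminant(X, y, priors="uniform").fit()
        mid = 0.5 * (res.class_means[0] + res.class_means[1])
        labels, post = res.classify(mid)
        assert abs(post[0, 0] - post[0, 1]) < 1e-9
        assert labels[0] == "a"

    def test_agrees_with_mahalanobis_oracle(self, rng):
        """Equal priors: classification equals minimum Mahalanobis distance."""
        mus = [np.zeros(4), np.array([2.0, 0, 0, 0]), np.array([0, 2.0, 1.0, 0])]
        X, y = [], []
        for lab, m in zip("abc", mus):
            X.append(rng.standard_normal((30, 4)) + m)
            y += [lab] * 30
        X = np.vstack(X)
        model = LinearDiscriminant(X, y, priors="uniform")
        res = model.fit()
        # oracle: pooled within-class covariance in the original space
        W = res.within_cov
        Winv = np.linalg.inv(W)
        samples = rng.standard_normal((100, 4)) * 1.5
        d2 = np.stack(
            [np.einsum("ij,jk,ik->i", samples - mu, Winv, samples - mu)
             for mu in res.class_means], axis=1,
        )
        oracle = np.array(res.classes, dtype=object)[d2.argmin(axis=1)]
        ours, _ = res.classify(samples)
        assert (ours == oracle).all()

    def test_panel_mismatch_raises(self, default_training):
        res = lda_fit(default_training)
        with pytest.raises(CoverageError):
            res.transform(np.zeros((2, 4)))


class TestLoocv:
    def test_perfectly_separated_classes(self):
        classes = tuple(
            ClassSpec(s.label, s.n, s.mean_fingerprint, cov_scale=0.2)
            for s in TrainingSimConfig().classes
        )  # >= 6 within-class SDs between means
        ts = simulate_training(TrainingSimConfig(classes=classes, seed=1))
        assert loocv(ts)["accuracy"] == 1.0

    def test_result_invariant_to_sample_order(self, default_training, rng):
        cv1 = loocv(default_training)
        perm = rng.permutation(len(default_training))
        from eaafinger import TrainingSet

        shuffled = TrainingSet(
            default_training.X[perm], default_training.labels[perm],
            taxa=default_training.taxa[perm],
        )
        cv2 = loocv(shuffled)
        assert cv1["accuracy"] == cv2["accuracy"]
        assert cv1["per_class"] == cv2["per_class"]

    def test_class_too_small_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 6))
        X -= X.mean(axis=1, keepdims=True)
        from eaafinger import TrainingSet

        ts = TrainingSet(X, ["a", "a", "b", "b", "b"], center=True)
        with pytest.raises(SampleSizeError):
            loocv(ts)


class TestEllipse:
    def test_unit_variance_circle_radius(self, rng):
        # whiten a sample so its covariance is exactly the identity
        Z = rng.standard_normal((500, 2))
        Z -= Z.mean(axis=0)
        L = np.linalg.cholesky(np.cov(Z.T))
        Z = Z @ np.linalg.inv(L).T
        ell = confidence_ellipse(Z, level=0.95)
        q95 = stats.chi2.ppf(0.95, 2)  # 5.991...
        assert ell.semimajor**2 == pytest.approx(q95, rel=1e-6)
        assert ell.semiminor**2 == pytest.approx(q95, rel=1e-6)

    def test_scale_equivariance(self, rng):
        Z = rng.standard_normal((50, 2)) @ np.array([[1.5, 0.3], [0.0, 0.7]])
        e1 = confidence_ellipse(Z)
        e2 = confidence_ellipse(2.0 * Z)
        assert e2.semimajor == pytest.approx(2 * e1.semimajor)
        assert e2.semiminor == pytest.approx(2 * e1.semiminor)

    def test_empirical_coverage(self, rng):
        """95% ellipse covers ~95% of a large Gaussian sample."""
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        L = np.linalg.cholesky(cov)
        Z = rng.standard_normal((10_000, 2)) @ L.T
        ell = confidence_ellipse(Z, level=0.95)
        mu = Z.mean(axis=0)
        S = np.cov(Z.T)
        d2 = np.einsum("ij,jk,ik->i", Z - mu, np.linalg.inv(S), Z - mu)
        inside = (d2 <= stats.chi2.ppf(0.95, 2)).mean()
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_degenerate_covariance_raises(self):
        Z = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(NumericalError, match="degenerate"):
            confidence_ellipse(Z)

    def test_invalid_level_rejected(self, rng):
        with pytest.raises(ValidationError):
            confidence_ellipse(rng.standard_normal((10, 2)), level=1.5)


class TestPersistence:
    def test_json_round_trip_is_bit_reproducible(self, default_training, tmp_path):
        res = lda_fit(default_training)
        path = tmp_path / "model.json"
        res.to_json(path)
        back = LDAResults.from_json(path)
        Z1 = res.transform(default_training.X)
        Z2 = back.transform(default_training.X)
        np.testing.assert_array_equal(Z1, Z2)
        assert back.classes == res.classes

    def test_summary_mentions_classes_and_loadings(self, default_training):
        text = lda_fit(default_training).summary()
        assert "bacteria" in text and "Thr" in text


def _energy_perm_p(A: np.ndarray, B: np.ndarray, n_perm: int, rng) -> float:
    """Two-sample energy-distance permutation p value."""
    from scipy.spatial.distance import cdist

    pooled = np.vstack([A, B])
    D = cdist(pooled, pooled)
    n_a = A.shape[0]

    def stat(mask_a):
        mask_b = ~mask_a
        return (
            2 * D[np.ix_(mask_a, mask_b)].mean()
            - D[np.ix_(mask_a, mask_a)].mean()
            - D[np.ix_(mask_b, mask_b)].mean()
        )

    base = np.zeros(len(pooled), dtype=bool)
    base[:n_a] = True
    obs = stat(base)
    hits = 0
    for _ in range(n_perm):
        hits += stat(rng.permutation(base)) >= obs
    return (1 + hits) / (n_perm + 1)


class TestProjectionUnderH0:
    def test_identical_cohorts_project_indistinguishably(self, rng):
        """GF and CVZ clouds simulated with identical settings are statistically
        indistinguishable in discriminant space (energy-distance permutation)."""
        from eaafinger import build_diet_profile, simulate_experiment, study_conditions

        ok = 0
        n_runs = 100
        for run in range(n_runs):
            table = simulate_experiment(study_conditions(f=0.0, seed=5000 + run))
            ts = simulate_training(TrainingSimConfig(seed=run))
            res = lda_fit(ts)
            fps = fingerprint_table(table.subset(group=["GF", "CVZ"]))
            Z = res.transform(fps.to_numpy())
            groups = np.array([ix[1] for ix in fps.index])
            p = _energy_perm_p(Z[groups == "GF"], Z[groups == "CVZ"], 199, rng)
            ok += p > 0.05
        assert ok / n_runs >= 0.90


class TestPipelineInvariance:
    def test_single_sample_shift_changes_nothing_downstream(self, h0_experiment):
        consumers = h0_experiment.subset(group=["GF", "CVZ"])
        fp1 = fingerprint_table(consumers)
        df = consumers.data.copy()
        one = df["sample_id"] == df["sample_id"].iloc[0]
        df.loc[one, "delta13c"] += 7.3
        from eaafinger import MeasurementTable

        fp2 = fingerprint_table(MeasurementTable(df))
        np.testing.assert_allclose(fp1.to_numpy(), fp2.to_numpy(), atol=1e-9)
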