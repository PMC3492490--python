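import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from sleepspace import (
    PooledCovarianceLDA,
    confusion_matrix_fractions,
    density_projection,
    fit_classifier,
    positive_predictive_value,
    train_test_split_protocol,
)


def _blobs(rng, means, n=200, cov=None):
    cov = np.eye(2) if cov is None else cov
    X = np.vstack([rng.multivariate_normal(m, cov, size=n) for m in means])
    y = np.concatenate([[f"S{i}"] * n for i in range(len(means))]).astype(object)
    return X, y


class TestPooledCovarianceLDA:
    def test_separated_blobs_high_training_accuracy(self, rng):
        X, y = _blobs(rng, [(-4, 0), (4, 0)], n=500)
        m = fit_classifier(X, y)
        assert np.mean(m.predict(X) == y) >= 0.99

    def test_posteriors_sum_to_one(self, rng):
        X, y = _blobs(rng, [(-1, 0), (1, 0), (0, 2)], n=50)
        m = fit_classifier(X, y)
        P = m.predict_proba(rng.normal(size=(40, 2)))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(P >= 0)

    def test_point_at_class_mean_with_equal_priors(self, rng):
        X, y = _blobs(rng, [(-3, -3), (3, 3)], n=100)
        m = fit_classifier(X, y)
        assert m.predict(m.means_[:1])[0] == m.classes_[0]

    def test_equal_prior_isotropic_is_nearest_centroid(self, rng):
        X, y = _blobs(rng, [(-2, 0), (2, 0), (0, 3)], n=300)
        m = fit_classifier(X, y)
        grid = rng.uniform(-5, 5, size=(500, 2))
        d = np.linalg.norm(grid[:, None, :] - m.means_[None], axis=2)
        # pooled covariance of isotropic blobs is ~isotropic: argmin distance
        nearest = m.classes_[np.argmin(d, axis=1)]
        agree = np.mean(m.predict(grid) == nearest)
        assert agree > 0.98  # disagreements only near boundaries

    def test_matches_brute_force_gaussian_density(self, rng):
        X, y = _blobs(rng, [(-2, 1), (2, -1)], n=150,
                      cov=np.array([[1.5, 0.4], [0.4, 0.8]]))
        m = fit_classifier(X, y)
        grid = rng.uniform(-6, 6, size=(300, 2))
        dens = np.column_stack(
            [
                p * multivariate_normal(mean, m.covariance_).pdf(grid)
                for mean, p in zip(m.means_, m.priors_)
            ]
        )
        expected = m.classes_[np.argmax(dens, axis=1)]
        np.testing.assert_array_equal(m.predict(grid), expected)

    def test_cross_check_against_sklearn(self, rng):
        # independent implementation of the same model: identical stagings
        X, y = _blobs(rng, [(-2, 0), (1, 1), (3, -2)], n=200)
        ours = fit_classifier(X, y, ridge=0.0)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y.astype(str))
        grid = rng.uniform(-6, 6, size=(400, 2))
        assert np.mean(ours.predict(grid).astype(str) == ref.predict(grid)) == 1.0

    def test_affine_invariance(self, rng):
        X, y = _blobs(rng, [(-2, 0), (2, 1)], n=200)
        grid = rng.uniform(-4, 4, size=(100, 2))
        base = fit_classifier(X, y).predict(grid)
        for _ in range(5):
            A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
            b = rng.normal(size=2)
            mapped = fit_classifier(X @ A.T + b, y).predict(grid @ A.T + b)
            np.testing.assert_array_equal(mapped, base)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_classifier(X, np.array(["WAKE"] * 10, dtype=object))

    def test_too_few_points_per_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array(["WAKE", "WAKE", "WAKE", "REM", "REM"], dtype=object)
        with pytest.raises(ValueError, match="REM"):
            fit_classifier(X, y)

    def test_non_finite_points_rejected(self, rng):
        X, y = _blobs(rng, [(-2, 0), (2, 0)], n=50)
        m = fit_classifier(X, y)
        with pytest.raises(ValueError):
            m.predict(np.array([[np.nan, 0.0]]))

    def test_duplicated_blob_classified_by_prior(self, rng):
        blob = rng.multivariate_normal((0, 0), np.eye(2), size=300)
        X = np.vstack([blob, blob[:100]])
        y = np.array(["A"] * 300 + ["B"] * 100, dtype=object)
        m = fit_classifier(X, y)
        # identical class distributions: the larger prior wins everywhere
        assert np.all(m.predict(rng.normal(size=(50, 2))) == "A")

    def test_json_roundtrip(self, rng, tmp_path):
        X, y = _blobs(rng, [(-2, 0), (2, 0)], n=50)
        m = fit_classifier(X, y)
        p = tmp_path / "model.json"
        m.save(p)
        back = PooledCovarianceLDA.load(p)
        grid = rng.normal(size=(30, 2))
        np.testing.assert_array_equal(back.predict(grid), m.predict(grid))


class TestPPV:
    def test_perfect_prediction(self):
        y = np.array(["WAKE", "REM", "NREM2"] * 4, dtype=object)
        out = positive_predictive_value(y, y)
        assert out["overall"] == 1.0
        assert all(v == 1.0 for v in out["per_stage"].values())

    def test_toy_count(self):
        pred = np.array(list("AAAAABBBBB"), dtype=object)
        manual = np.array(list("AAABBBBBAA"), dtype=object)
        assert positive_predictive_value(pred, manual)["overall"] == 0.6

    def test_never_predicted_stage_is_missing_not_zero(self):
        pred = np.array(["WAKE"] * 5, dtype=object)
        manual = np.array(["WAKE", "WAKE", "REM", "REM", "REM"], dtype=object)
        out = positive_predictive_value(pred, manual)
        assert np.isnan(out["per_stage"]["REM"])
        assert out["per_stage"]["WAKE"] == pytest.approx(0.4)

    def test_random_staging_matches_analytic_chance(self, rng):
        # independent pred/manual: P(agree) = sum_s p_s q_s
        p = np.array([0.3, 0.1, 0.35, 0.15, 0.1])
        q = np.array([0.2, 0.2, 0.3, 0.2, 0.1])
        stages = np.array(["WAKE", "NREM1", "NREM2", "NREM3", "REM"], dtype=object)
        n = 200_000
        pred = rng.choice(stages, p=p, size=n)
        manual = rng.choice(stages, p=q, size=n)
        expected = float(np.dot(p, q))
        got = positive_predictive_value(pred, manual)["overall"]
        assert got == pytest.approx(expected, abs=0.005)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            positive_predictive_value(np.array(["A"]), np.array(["A", "B"]))


class TestConfusion:
    def test_rows_sum_to_one(self, rng):
        stages = np.array(["WAKE", "NREM2", "REM"], dtype=object)
        pred = rng.choice(stages, size=500)
        manual = rng.choice(stages, size=500)
        mat, order = confusion_matrix_fractions(pred, manual)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)
        assert order == ["WAKE", "NREM2", "REM"]

    def test_diagonal_for_perfect_prediction(self):
        y = np.array(["WAKE", "REM"] * 10, dtype=object)
        mat, _ = confusion_matrix_fractions(y, y)
        np.testing.assert_allclose(mat, np.eye(2))


class TestTrainTestProtocol:
    def test_overlapping_ids_rejected(self, rng):
        X, y = _blobs(rng, [(-2, 0), (2, 0)], n=20)
        subjects = {0: (X, y), 1: (X, y)}
        with pytest.raises(ValueError, match="overlap"):
            train_test_split_protocol(subjects, [0, 1], [1])

    def test_held_out_ppv_close_to_training_ppv(self, rng):
        # all subjects drawn from one generative model
        means = [(-3, 0), (0, 2.5), (3, 0)]
        subjects = {i: _blobs(rng, means, n=150) for i in range(6)}
        out = train_test_split_protocol(subjects, [0, 1, 2, 3], [4, 5])
        X_tr = np.vstack([subjects[i][0] for i in range(4)])
        y_tr = np.concatenate([subjects[i][1] for i in range(4)])
        train_ppv = positive_predictive_value(out["model"].predict(X_tr), y_tr)
        assert abs(out["ppv"]["overall"] - train_ppv["overall"]) < 0.05

    def test_single_stage_test_subject(self, rng):
        X, y = _blobs(rng, [(-4, 0), (4, 0)], n=100)
        test_X = rng.multivariate_normal((-4, 0), np.eye(2), size=50)
        subjects = {0: (X, y), 1: (test_X, np.array(["S0"] * 50, dtype=object))}
        out = train_test_split_protocol(subjects, [0], [1])
        # S1 never predicted and absent from the test labels: missing, not 0
        assert np.isnan(out["ppv"]["per_stage"].get("S1", float("nan")))
        assert out["ppv"]["per_stage"]["S0"] > 0.9


class TestDensityProjection:
    def test_standard_normal_density_at_zero(self, rng):
        x = rng.normal(size=(10_000, 2))
        grid, dens = density_projection(x, axis=0)
        at0 = dens[np.argmin(np.abs(grid))]
        assert at0 == pytest.approx(0.3989, abs=0.02)

    def test_integrates_to_one(self, rng):
        x = rng.normal(size=(500, 2))
        grid, dens = density_projection(x, axis=1)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_two_point_sample_matches_closed_form_mixture(self):
        # a 2-point KDE is exactly the symmetric mixture of two kernels
        # (Silverman's bandwidth is wide enough here that they merge into a
        # single symmetric bump centred between the points)
        pts = np.array([[-2.0, 0.0], [2.0, 0.0]])
        grid, dens = density_projection(pts, axis=0)
        np.testing.assert_allclose(dens, dens[::-1], atol=1e-12)  # symmetry
        bw = np.sqrt(8.0) * (2 * 3 / 4) ** (-1 / 5)  # silverman, n=2, d=1
        mixture = 0.5 * (
            np.exp(-((grid + 2) ** 2) / (2 * bw**2))
            + np.exp(-((grid - 2) ** 2) / (2 * bw**2))
        ) / (bw * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(dens, mixture, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            density_projection(np.array([[0.0, 0.0]]), axis=0)
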