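"""Probability-based sleep staging in the 2-D band-ratio state space.

Stages are modelled as Gaussian classes with a shared (pooled) covariance —
linear discriminant analysis used as a discrete classifier. The estimator
follows the scikit-learn protocol (fit / predict / predict_proba) so it
composes with sklearn pipelines and model selection; the module-level
functions are thin wrappers kept for script use.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io import STAGES
from .spectral import BandRatioPair, DEFAULT_BANDS, hann_smooth

_STAGE_RANK = {s: i for i, s in enumerate(STAGES)}


def _stage_sort_key(label: str):
    # canonical stage order first, anything else after, alphabetically
    return (0, _STAGE_RANK[label]) if label in _STAGE_RANK else (1, label)


class PooledCovarianceLDA(ClassifierMixin, BaseEstimator):
    """Gaussian classifier with per-class means and one pooled covariance.

    Equivalent to classic LDA: the shared covariance makes all decision
    boundaries linear. Posteriors come from the class-conditional Gaussian
    densities weighted by empirical priors. A ridge of ``ridge`` x trace is
    added to the pooled covariance diagonal for numerical stability on
    near-degenerate clusters.

    Parameters
    ----------
    ridge : float, default 1e-6
        Fraction of the covariance trace added to its diagonal.

    Attributes
    ----------
    classes_ : ndarray of str — in canonical stage order.
    means_ : ndarray (n_classes, 2)
    covariance_ : ndarray (2, 2) — pooled, after ridge.
    priors_ : ndarray (n_classes,) — empirical class frequencies.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object), dtype=float)
        classes = sorted(set(y), key=_stage_sort_key)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to fit a discriminant")
        counts = {c: int(np.sum(y == c)) for c in classes}
        thin = [c for c, n in counts.items() if n < 3]
        if thin:
            raise ValueError(f"need >= 3 points per class; too few for {thin}")
        n, d = X.shape
        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        pooled = np.zeros((d, d))
        for i, c in enumerate(classes):
            r = X[y == c] - means[i]
            pooled += r.T @ r
        pooled /= n - len(classes)
        pooled += self.ridge * np.trace(pooled) * np.eye(d)
        eigvals = np.linalg.eigvalsh(pooled)
        if eigvals[0] <= 0:
            raise ValueError("degenerate pooled covariance (zero eigenvalue)")
        self.classes_ = np.array(classes, dtype=object)
        self.means_ = means
        self.covariance_ = pooled
        self.priors_ = np.array([counts[c] / n for c in classes])
        self._precision = np.linalg.inv(pooled)
        self._logdet = float(np.linalg.slogdet(pooled)[1])
        return self

    def _log_joint(self, X) -> np.ndarray:
        """log p(x | class) + log prior, per point and class."""
        check_is_fitted(self, "classes_")
        X = check_array(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite coordinates")
        d = X.shape[1]
        out = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            r = X - self.means_[i]
            maha = np.einsum("ij,jk,ik->i", r, self._precision, r)
            out[:, i] = (
                -0.5 * (maha + self._logdet + d * np.log(2 * np.pi))
                + np.log(self.priors_[i])
            )
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Per-class posterior probabilities (rows sum to 1)."""
        lj = self._log_joint(X)
        lj -= lj.max(axis=1, keepdims=True)
        p = np.exp(lj)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Stage of maximum posterior; exact ties go to the larger prior,
        then to the earlier stage in canonical order."""
        lj = self._log_joint(X)
        best = lj.max(axis=1, keepdims=True)
        # tie-break: among argmax columns prefer larger prior, then the
        # earlier stage in the canonical order encoded in classes_
        k = len(self.classes_)
        order = sorted(range(k), key=lambda i: (self.priors_[i], -i))
        tie_bonus = np.empty(k, dtype=int)
        tie_bonus[order] = np.arange(k)
        keys = (lj == best) * (1 + tie_bonus)
        idx = np.argmax(keys, axis=1)
        return self.classes_[idx]

    def to_dict(self, bands: BandRatioPair | None = None) -> dict:
        check_is_fitted(self, "classes_")
        d = {
            "classes": list(self.classes_),
            "means": self.means_.tolist(),
            "covariance": self.covariance_.tolist(),
            "priors": self.priors_.tolist(),
            "ridge": self.ridge,
        }
        if bands is not None:
            d["bands"] = bands.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PooledCovarianceLDA":
        m = cls(ridge=d.get("ridge", 1e-6))
        m.classes_ = np.array(d["classes"], dtype=object)
        m.means_ = np.asarray(d["means"], dtype=float)
        m.covariance_ = np.asarray(d["covariance"], dtype=float)
        m.priors_ = np.asarray(d["priors"], dtype=float)
        m._precision = np.linalg.inv(m.covariance_)
        m._logdet = float(np.linalg.slogdet(m.covariance_)[1])
        return m

    def save(self, path: str | Path, bands: BandRatioPair | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(bands), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PooledCovarianceLDA":
        return cls.from_dict(json.loads(Path(path).read_text()))


class BandRatioTransform(TransformerMixin, BaseEstimator):
    """Sklearn transformer: epoch power spectra -> smoothed 2-D coordinates.

    ``X`` is an (n_epochs, n_bins) matrix of one-sided spectral power whose
    bin centers are ``freqs``; the transform reproduces
    :func:`sleepspace.spectral.ratio_coordinates` followed by the running
    Hann average, so it can sit in front of :class:`PooledCovarianceLDA`
    in a Pipeline.
    """

    def __init__(
        self,
        freqs=None,
        bands: BandRatioPair = DEFAULT_BANDS,
        smooth_window: int = 10,
        normalize: bool = True,
    ):
        self.freqs = freqs
        self.bands = bands
        self.smooth_window = smooth_window
        self.normalize = normalize

    def fit(self, X, y=None):
        if self.freqs is None:
            raise ValueError("freqs (spectral bin centers) must be provided")
        self.n_features_in_ = np.atleast_2d(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        from .spectral import EpochSpectra, ratio_coordinates

        check_is_fitted(self, "n_features_in_")
        spectra = EpochSpectra(
            freqs=np.asarray(self.freqs, dtype=float),
            power=np.atleast_2d(np.asarray(X, dtype=float)),
            epoch_length=float("nan"),
            sampling_rate=float("nan"),
        )
        coords = ratio_coordinates(spectra, self.bands, normalize=self.normalize)
        if self.smooth_window and self.smooth_window > 1 and len(coords) > 1:
            coords = hann_smooth(coords, self.smooth_window)
        return coords


# ---------------------------------------------------------------------------
# functional wrappers and evaluation


def fit_classifier(points, labels, ridge: float = 1e-6) -> PooledCovarianceLDA:
    """Fit the pooled-covariance stage classifier on 2-D coordinates."""
    return PooledCovarianceLDA(ridge=ridge).fit(points, labels)


def classify(model: PooledCovarianceLDA, points) -> np.ndarray:
    return model.predict(points)


def posterior(model: PooledCovarianceLDA, points) -> np.ndarray:
    return model.predict_proba(points)


def positive_predictive_value(pred, manual) -> dict:
    """Agreement of automatic with manual staging.

    ``overall`` is the fraction of epochs where the prediction matches the
    manual score. ``per_stage[s]`` conditions on the *predicted* stage:
    among epochs the classifier calls s, the fraction manually scored s.
    Stages never predicted are reported as NaN (missing), never as 0.
    """
    pred = np.asarray(pred, dtype=object)
    manual = np.asarray(manual, dtype=object)
    if pred.shape != manual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {manual.shape}")
    if len(pred) == 0:
        raise ValueError("empty staging")
    per_stage: dict[str, float] = {}
    for s in sorted(set(pred) | set(manual), key=_stage_sort_key):
        mask = pred == s
        per_stage[s] = float(np.mean(manual[mask] == s)) if mask.any() else float("nan")
    return {"overall": float(np.mean(pred == manual)), "per_stage": per_stage}


def confusion_matrix_fractions(pred, manual) -> tuple[np.ndarray, list[str]]:
    """Row-normalized confusion matrix; rows = manual stage, cols = predicted.

    Each row sums to 1 (rows for stages absent from the manual score are
    NaN). Returns (matrix, stage order).
    """
    pred = np.asarray(pred, dtype=object)
    manual = np.asarray(manual, dtype=object)
    if pred.shape != manual.shape:
        raise ValueError("length mismatch")
    stages = sorted(set(pred) | set(manual), key=_stage_sort_key)
    mat = np.zeros((len(stages), len(stages)))
    for i, sm in enumerate(stages):
        row_mask = manual == sm
        if not row_mask.any():
            mat[i] = np.nan
            continue
        for j, sp in enumerate(stages):
            mat[i, j] = np.mean(pred[row_mask] == sp)
    return mat, stages


def train_test_split_protocol(
    subjects: dict, train_ids, test_ids, ridge: float = 1e-6
) -> dict:
    """Fit on one subject group, evaluate on held-out subjects.

    ``subjects`` maps subject id -> (points, labels). Train and test id
    sets must be disjoint (guards against the protocol violation of
    testing on training data).
    """
    train_ids, test_ids = list(train_ids), list(test_ids)
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"train/test ids overlap: {sorted(overlap)}")
    X_tr = np.vstack([np.asarray(subjects[i][0]) for i in train_ids])
    y_tr = np.concatenate([np.asarray(subjects[i][1], dtype=object) for i in train_ids])
    model = fit_classifier(X_tr, y_tr, ridge=ridge)
    X_te = np.vstack([np.asarray(subjects[i][0]) for i in test_ids])
    y_te = np.concatenate([np.asarray(subjects[i][1], dtype=object) for i in test_ids])
    ppv = positive_predictive_value(model.predict(X_te), y_te)
    return {"model": model, "ppv": ppv, "n_train": len(y_tr), "n_test": len(y_te)}


def density_projection(
    points: np.ndarray, axis: int, grid_size: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """1-D Gaussian kernel density of one state-space coordinate.

    Bandwidth by Silverman's rule. Returns (grid, density); the density
    integrates to ~1 over the grid (extended 3 bandwidths past the data
    range).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x = points[:, axis]
    if len(x) < 2:
        raise ValueError("need at least 2 points for a density estimate")
    kde = gaussian_kde(x, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
    return grid, kde(grid)
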