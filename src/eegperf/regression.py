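"""PCA-based linear regression from stacked log-PSD features to behavior.

The feature matrix stacks the 40 frequency bins of k channels
(channel-major) into an n x 40k matrix. An eigendecomposition of the
column-centered sample covariance retains every component explaining at
least 1% of the total variance; ordinary least squares (with intercept)
maps the projections onto the behavioral series. The eigenbasis and the
centering means always come from training data only, so cross-validated
estimates see no test-set statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BehaviorSeries, PSDTimeSeries, STANDARD_MONTAGE
from .errors import ConfigurationError, DataError

VARIANCE_THRESHOLD = 0.01


@dataclass
class FeatureMatrix:
    """Stacked log-PSD features: column block j holds channel j's 40 bins."""

    X: np.ndarray
    channels: list[str]
    n_freqs: int

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]


@dataclass
class EigenBasis:
    """Retained eigenvectors of the training feature covariance."""

    V: np.ndarray            # (d, M) orthonormal columns, descending eigenvalue
    eigenvalues: np.ndarray  # (M,)
    means: np.ndarray        # (d,) training column means
    total_variance: float    # sum of all covariance eigenvalues (= trace)
    variance_threshold: float = VARIANCE_THRESHOLD

    @property
    def n_components(self) -> int:
        return self.V.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) @ self.V


@dataclass
class SpectralRegressionModel:
    """Eigenbasis + OLS coefficients mapping stacked log-PSD to behavior."""

    basis: EigenBasis
    beta: np.ndarray
    intercept: float
    channels: list[str]
    metric: str = ""

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        return self.basis.project(X) @ self.beta + self.intercept

    @property
    def feature_weights(self) -> np.ndarray:
        """Weight vector in the original channel-frequency space (V @ beta)."""
        return self.basis.V @ self.beta


def stack_features(psd: PSDTimeSeries, channels) -> FeatureMatrix:
    """Stack per-channel log-PSD into an n x (n_freqs * k) matrix."""
    channels = list(channels)
    idx = [psd.channel_index(c) for c in channels]
    n_f = len(psd.freqs)
    X = psd.logpower[:, idx, :].reshape(psd.n_epochs, len(idx) * n_f)
    return FeatureMatrix(np.ascontiguousarray(X, dtype=float), channels, n_f)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def fit_basis(X, variance_threshold: float = VARIANCE_THRESHOLD) -> EigenBasis:
    """Eigendecomposition of the column-centered covariance; retain all
    components whose eigenvalue share is at least ``variance_threshold``.

    If no component reaches the threshold (e.g. near-isotropic input) the
    single largest component is retained.
    """
    Xm = _as_matrix(X)
    n, d = Xm.shape
    if n < 2:
        raise DataError("need at least two rows to estimate a covariance")
    means = Xm.mean(axis=0)
    Xc = Xm - means
    C = (Xc.T @ Xc) / (n - 1)
    total = float(np.trace(C))
    if total <= 0:
        raise DataError("feature matrix has zero variance")
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    share = w / total
    m = int(np.sum(share >= variance_threshold))
    m = max(m, 1)
    return EigenBasis(np.ascontiguousarray(V[:, :m]), w[:m].copy(), means,
                      total, variance_threshold)


def fit_model(X, basis: EigenBasis, y, metric: str = "",
              channels=None) -> SpectralRegressionModel:
    """Ordinary least squares of behavior on the eigenbasis projections."""
    Xm = _as_matrix(X)
    yv = y.values if isinstance(y, BehaviorSeries) else np.asarray(y, dtype=float)
    if isinstance(y, BehaviorSeries) and not metric:
        metric = y.name
    if isinstance(X, FeatureMatrix) and channels is None:
        channels = X.channels
    if len(yv) != Xm.shape[0]:
        raise DataError("feature rows and behavior samples must align")
    P = basis.project(Xm)
    n, m = P.shape
    if n < m + 1:
        raise DataError(f"{n} rows cannot identify {m} coefficients + intercept")
    A = np.column_stack([np.ones(n), P])
    coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
    return SpectralRegressionModel(basis, coef[1:], float(coef[0]),
                                   list(channels or []), metric)


def estimate(model: SpectralRegressionModel, psd: PSDTimeSeries) -> BehaviorSeries:
    """Apply a fitted model to a PSD time series (training centering reused)."""
    missing = [c for c in model.channels if c not in psd.channel_names]
    if missing:
        raise ConfigurationError(f"PSD lacks channels required by model: {missing}")
    feats = stack_features(psd, model.channels)
    yhat = model.predict_features(feats.X)
    name = f"{model.metric}_est" if model.metric else "estimate"
    return BehaviorSeries(name, psd.epoch_times, yhat, psd.block_ids)


def fit_standard(psd: PSDTimeSeries, y: BehaviorSeries,
                 channels=STANDARD_MONTAGE,
                 variance_threshold: float = VARIANCE_THRESHOLD) -> SpectralRegressionModel:
    """Fit the standard fixed-montage scheme (midline Fz, Cz, Pz, Oz)."""
    missing = [c for c in channels if c not in psd.channel_names]
    if missing:
        raise ConfigurationError(f"montage lacks required channel(s): {missing}")
    feats = stack_features(psd, channels)
    basis = fit_basis(feats, variance_threshold)
    return fit_model(feats, basis, y)
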