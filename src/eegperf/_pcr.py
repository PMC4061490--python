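"""Fast evaluation of the channel-selection criterion J = 1/RMSE.

The floating channel search evaluates hundreds of channel subsets; each
probe requires the stack -> center -> PCA -> OLS -> predict pipeline on an
inner cross-validation split of the training blocks. To keep a
full-scale search (32 candidates, 500 probes per fold) tractable on one
CPU, the evaluator

* caches the column means and the full cross-channel feature covariance
  once, so a probe's subset covariance is a cheap submatrix gather;
* fits the (unsupervised) eigenbasis of a probe once on all training
  blocks and cross-validates only the regression stage block-by-block
  (see the ``inner-cv`` protocol below); a fully nested variant refits
  the basis per inner fold;
* solves for the top eigenpairs with a deterministic randomized subspace
  iteration when the subset dimension is large, with an exact ``eigh``
  fallback below ``exact_dim`` and an adaptive guard when the retained
  component count approaches the subspace size. The 1%-of-variance
  retention rule is always applied against the exact total variance
  (the covariance trace).

Protocols
---------
``inner-cv`` (default)
    Eigenbasis and centering from all provided (training) blocks; the OLS
    stage is leave-one-block-out cross-validated; J is one over the RMSE
    of the concatenated held-out predictions.
``inner-cv-nested``
    Basis, centering and OLS all refit per inner fold (strictly nested).
``train-fit``
    Fit and evaluate on all provided epochs (training-fit RMSE; decreases
    monotonically with channel count, so backward steps become vacuous).
"""
from __future__ import annotations

import warnings

import numpy as np

from .containers import BehaviorSeries, PSDTimeSeries
from .errors import DataError, ParameterError
from .regression import VARIANCE_THRESHOLD, stack_features

RMSE_CAP = 1e12
EXACT_DIM = 200


def criterion_from_predictions(y, y_est, cap: float = RMSE_CAP) -> float:
    """J = 1 / sqrt(mean((y - y_est)^2)); a zero RMSE returns ``cap``."""
    y = np.asarray(y, dtype=float)
    y_est = np.asarray(y_est, dtype=float)
    if y.shape != y_est.shape or y.size == 0:
        raise DataError("y and y_est must be equal-length, nonempty")
    rmse = float(np.sqrt(np.mean((y - y_est) ** 2)))
    if rmse == 0.0:
        warnings.warn("criterion RMSE is exactly zero; returning cap",
                      RuntimeWarning, stacklevel=2)
        return cap
    return 1.0 / rmse


def top_components(C: np.ndarray, total: float, threshold: float,
                   exact_dim: int = EXACT_DIM, seed: int = 0,
                   oversample: int = 48, power_iters: int = 2):
    """Eigenpairs of ``C`` whose eigenvalue share (of ``total``) reaches
    ``threshold``; at least one component is always returned.

    Exact ``eigh`` for small matrices; deterministic randomized subspace
    iteration (Halko-style range finder) above ``exact_dim``, escalating
    the subspace and finally falling back to exact decomposition if the
    retained count gets close to the subspace size.
    """
    d = C.shape[0]
    if total <= 0:
        raise DataError("covariance has non-positive total variance")
    if d <= exact_dim:
        w, V = np.linalg.eigh(C)
        w, V = w[::-1], V[:, ::-1]
        m = max(1, int(np.sum(w / total >= threshold)))
        return w[:m], V[:, :m]
    l = min(d, oversample)
    while True:
        rng = np.random.default_rng(seed)
        Y = C @ rng.standard_normal((d, l))
        for _ in range(power_iters):
            Q, _ = np.linalg.qr(Y)
            Y = C @ Q
        Q, _ = np.linalg.qr(Y)
        B = Q.T @ C @ Q
        w, U = np.linalg.eigh(B)
        w, U = w[::-1], U[:, ::-1]
        m = max(1, int(np.sum(w / total >= threshold)))
        if m <= l - 8 or l >= d:
            return w[:m], Q @ U[:, :m]
        if 2 * l >= d:  # subspace nearly full: just be exact
            w, V = np.linalg.eigh(C)
            w, V = w[::-1], V[:, ::-1]
            m = max(1, int(np.sum(w / total >= threshold)))
            return w[:m], V[:, :m]
        l = min(d, 2 * l)


class CriterionEvaluator:
    """Callable computing J(channel subset) under a fixed evaluation protocol."""

    def __init__(self, psd: PSDTimeSeries, y, candidates=None,
                 protocol: str = "inner-cv",
                 variance_threshold: float = VARIANCE_THRESHOLD,
                 exact_dim: int = EXACT_DIM, cap: float = RMSE_CAP):
        self.candidates = (list(candidates) if candidates is not None
                           else list(psd.channel_names))
        self.variance_threshold = variance_threshold
        self.exact_dim = exact_dim
        self.cap = cap
        yv = y.values if isinstance(y, BehaviorSeries) else np.asarray(y, dtype=float)
        if len(yv) != psd.n_epochs:
            raise DataError("behavior series must be aligned to PSD epochs")
        if protocol not in ("inner-cv", "inner-cv-nested", "train-fit"):
            raise ParameterError(f"unknown criterion protocol {protocol!r}")
        self.protocol = protocol
        feats = stack_features(psd, self.candidates)
        self.n_freqs = feats.n_freqs
        self._index = {c: i for i, c in enumerate(self.candidates)}
        self.y = yv
        blocks = np.unique(psd.block_ids)
        if protocol in ("inner-cv", "inner-cv-nested") and blocks.size < 2:
            raise ParameterError("inner-cv protocols need at least two blocks")
        self._fold_rows = ([(np.flatnonzero(psd.block_ids != b),
                             np.flatnonzero(psd.block_ids == b))
                            for b in blocks]
                           if protocol != "train-fit"
                           else [(np.arange(psd.n_epochs), np.arange(psd.n_epochs))])

        X = feats.X
        n = X.shape[0]
        if protocol == "inner-cv-nested":
            self._X = X  # nested mode recomputes moments per probe/fold
            self._mu = None
        else:
            self._mu = X.mean(axis=0)
            Xc = X - self._mu
            self._C = (Xc.T @ Xc) / (n - 1)
            # Fortran order: per-channel column blocks become contiguous,
            # so projections avoid a per-probe gather copy.
            self._Xc = np.asfortranarray(Xc)
            self._traces = np.array([
                np.trace(self._C[c * self.n_freqs:(c + 1) * self.n_freqs,
                                 c * self.n_freqs:(c + 1) * self.n_freqs])
                for c in range(len(self.candidates))])
            self._dim_idx = [np.arange(c * self.n_freqs, (c + 1) * self.n_freqs)
                             for c in range(len(self.candidates))]

    # -- shared-basis path ------------------------------------------------
    def _predictions_shared(self, ch_idx) -> np.ndarray:
        nf = self.n_freqs
        idx = np.concatenate([self._dim_idx[c] for c in ch_idx])
        Cs = self._C[np.ix_(idx, idx)]
        total = float(self._traces[list(ch_idx)].sum())
        w, V = top_components(Cs, total, self.variance_threshold,
                              self.exact_dim)
        # projections under shared centering, channel block by channel block
        n, m = self.y.size, V.shape[1]
        P = np.zeros((n, m))
        for j, c in enumerate(ch_idx):
            P += self._Xc[:, c * nf:(c + 1) * nf] @ V[j * nf:(j + 1) * nf]
        # intercept-augmented normal equations, assembled per fold by
        # subtracting the held-out block's Gram contribution
        y = self.y
        G_all = P.T @ P
        b_all = P.T @ y
        s_all = P.sum(axis=0)
        ysum_all = float(y.sum())
        yhat = np.empty_like(y)
        for train, ev in self._fold_rows:
            if train.size == n:  # train-fit protocol
                G, bvec, svec, ysum, ntr = G_all, b_all, s_all, ysum_all, n
            else:
                Pe, ye = P[ev], y[ev]
                G = G_all - Pe.T @ Pe
                bvec = b_all - Pe.T @ ye
                svec = s_all - Pe.sum(axis=0)
                ysum = ysum_all - float(ye.sum())
                ntr = n - ev.size
            A = np.empty((m + 1, m + 1))
            A[0, 0] = ntr
            A[0, 1:] = svec
            A[1:, 0] = svec
            A[1:, 1:] = G
            rhs = np.concatenate([[ysum], bvec])
            try:
                coef = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                coef, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            yhat[ev] = P[ev] @ coef[1:] + coef[0]
        return yhat

    # -- nested path -------------------------------------------------------
    def _predictions_nested(self, ch_idx) -> np.ndarray:
        idx = np.concatenate([np.arange(c * self.n_freqs, (c + 1) * self.n_freqs)
                              for c in ch_idx])
        Xs = self._X[:, idx]
        yhat = np.empty_like(self.y)
        for train, ev in self._fold_rows:
            Xtr = Xs[train]
            mu = Xtr.mean(axis=0)
            Xc = Xtr - mu
            C = (Xc.T @ Xc) / (train.size - 1)
            total = float(np.trace(C))
            if total <= 0:
                raise DataError("subset features have zero variance")
            w, V = top_components(C, total, self.variance_threshold,
                                  self.exact_dim)
            P = Xc @ V
            A = np.column_stack([np.ones(train.size), P])
            coef, *_ = np.linalg.lstsq(A, self.y[train], rcond=None)
            yhat[ev] = (Xs[ev] - mu) @ V @ coef[1:] + coef[0]
        return yhat

    def predictions(self, subset) -> np.ndarray:
        """Held-out predictions for a channel subset under the protocol."""
        if len(subset) == 0:
            raise ParameterError("criterion subset must be nonempty")
        ch_idx = [self._index[c] for c in subset]
        if self.protocol == "inner-cv-nested":
            return self._predictions_nested(ch_idx)
        return self._predictions_shared(ch_idx)

    def __call__(self, subset) -> float:
        return criterion_from_predictions(self.y, self.predictions(subset),
                                          cap=self.cap)
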