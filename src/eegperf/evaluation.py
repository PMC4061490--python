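"""Leave-one-block-out cross-validation, significance, and model transfer.

Models are always trained on five of the six experimental blocks and
evaluated on the held-out block, which — together with block-bounded 90 s
smoothing — guarantees a temporal separation between training and test
sets of roughly the smoothing window. Significance of the full-session
correlation is established against a permutation null: the estimated
series is randomly permuted, re-smoothed with the same 90 s filter (so the
null shares the autocorrelation that inflates spurious correlations of
low-pass signals), and correlated with the actual behavior; a Gaussian is
fit to the permuted correlation values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import BehaviorSeries, PSDTimeSeries, STANDARD_MONTAGE
from .errors import ConfigurationError, DataError, ParameterError
from .regression import (SpectralRegressionModel, VARIANCE_THRESHOLD, estimate,
                         fit_basis, fit_model, stack_features)
from .sffs import (CriterionEvaluator, DEFAULT_K_MAX, DEFAULT_MAX_ITER,
                   SFFSResult, sffs_select)
from .smoothing import DEFAULT_WINDOW_S, smooth_series


def pearson_r(y, y_est) -> float:
    """Pearson's correlation coefficient between actual and estimated behavior."""
    y = np.asarray(y, dtype=float)
    y_est = np.asarray(y_est, dtype=float)
    if y.shape != y_est.shape or y.ndim != 1:
        raise DataError("inputs must be equal-length 1-D arrays")
    if y.size < 3:
        raise DataError("need at least three samples")
    if np.ptp(y) == 0 or np.ptp(y_est) == 0:
        raise DataError("correlation undefined for a constant series")
    yc = y - y.mean()
    ec = y_est - y_est.mean()
    return float((yc @ ec) / np.sqrt((yc @ yc) * (ec @ ec)))


def normalized_rmse(y, y_est, sd_ref: float | None = None) -> float:
    """RMSE normalized by the standard deviation of the actual behavior.

    With ``sd_ref=None`` the population standard deviation of ``y`` is used,
    so the constant mean predictor scores exactly 1.
    """
    y = np.asarray(y, dtype=float)
    y_est = np.asarray(y_est, dtype=float)
    if y.shape != y_est.shape or y.size == 0:
        raise DataError("inputs must be equal-length, nonempty")
    if sd_ref is None:
        sd_ref = float(np.std(y))
    if sd_ref <= 0:
        raise ParameterError("sd_ref must be positive")
    return float(np.sqrt(np.mean((y - y_est) ** 2)) / sd_ref)


@dataclass
class NullDistribution:
    """Gaussian fit to permuted-estimate correlation coefficients."""

    r_values: np.ndarray
    mean: float
    sd: float
    alpha: float
    threshold: float
    sided: str = "greater"
    n_perm: int = 0

    def p_value(self, r_obs: float) -> float:
        z = (r_obs - self.mean) / self.sd
        if self.sided == "greater":
            return float(stats.norm.sf(z))
        return float(2.0 * stats.norm.sf(abs(z)))


def permutation_significance(y, y_est, times=None, block_ids=None,
                             n_perm: int = 1000,
                             window: float = DEFAULT_WINDOW_S,
                             alpha: float = 0.05, seed=None,
                             sided: str = "greater",
                             use_empirical_quantile: bool = False):
    """Permutation null for the behavior/estimate correlation.

    Returns ``(null_distribution, p_value)`` for the observed correlation.
    ``seed`` (int or numpy Generator) is required for reproducibility.
    """
    if seed is None:
        raise ParameterError("a seed is required for the permutation test")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse null estimate",
                      RuntimeWarning, stacklevel=2)
    if sided not in ("greater", "two-sided"):
        raise ParameterError("sided must be 'greater' or 'two-sided'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    yv = y.values if isinstance(y, BehaviorSeries) else np.asarray(y, dtype=float)
    ev = y_est.values if isinstance(y_est, BehaviorSeries) else np.asarray(y_est, dtype=float)
    if times is None and isinstance(y_est, BehaviorSeries):
        times = y_est.times
    if block_ids is None and isinstance(y_est, BehaviorSeries):
        block_ids = y_est.block_ids
    if times is None:
        times = np.arange(yv.size, dtype=float)
    times = np.asarray(times, dtype=float)

    r_obs = pearson_r(yv, ev)
    null_r = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(ev)
        perm = smooth_series(times, perm, window=window, block_ids=block_ids)
        null_r[i] = pearson_r(yv, perm)
    mu = float(null_r.mean())
    sd = float(null_r.std(ddof=1))
    if use_empirical_quantile:
        q = 1.0 - alpha if sided == "greater" else 1.0 - alpha / 2.0
        threshold = float(np.quantile(null_r, q))
    else:
        z = stats.norm.isf(alpha) if sided == "greater" else stats.norm.isf(alpha / 2.0)
        threshold = mu + z * sd
    null = NullDistribution(null_r, mu, sd, alpha, threshold, sided, n_perm)
    return null, null.p_value(r_obs)


@dataclass
class CVResult:
    """Full-session cross-validated estimate and its summary statistics."""

    scheme: str
    metric: str
    fold_blocks: list
    models: list
    y: np.ndarray
    y_est: np.ndarray
    times: np.ndarray
    block_ids: np.ndarray
    fold_r: list
    overall_r: float
    nrmse: float
    null: NullDistribution | None = None
    p: float | None = None
    sffs_results: list = field(default_factory=list)
    seed: int | None = None

    @property
    def threshold(self) -> float | None:
        return None if self.null is None else self.null.threshold

    @property
    def significant(self) -> bool | None:
        if self.null is None:
            return None
        return self.overall_r > self.null.threshold

    @property
    def representative_subset(self) -> tuple | None:
        """Channels of the fold whose selection criterion peaked highest."""
        if not self.sffs_results:
            return None
        best = max(self.sffs_results, key=lambda r: r.best_J)
        return best.best_subset

    def estimate_series(self) -> BehaviorSeries:
        return BehaviorSeries(f"{self.metric}_est", self.times, self.y_est,
                              self.block_ids)


def align_behavior(psd: PSDTimeSeries, series: BehaviorSeries) -> BehaviorSeries:
    """Sample a behavior series at the PSD epoch centers (nearest time,
    within the same block)."""
    return series.resample_to(psd.epoch_times, psd.block_ids)


def loo_block_cv(psd: PSDTimeSeries, y: BehaviorSeries, scheme: str = "standard",
                 candidates=None, standard_channels=STANDARD_MONTAGE,
                 variance_threshold: float = VARIANCE_THRESHOLD,
                 k_max: int = DEFAULT_K_MAX, max_iter: int = DEFAULT_MAX_ITER,
                 protocol: str = "inner-cv", n_perm: int = 1000,
                 alpha: float = 0.05, seed=None, smoothing_window: float = DEFAULT_WINDOW_S,
                 significance: bool = True) -> CVResult:
    """Leave-one-block-out cross-validation of either modeling scheme.

    ``y`` must already be aligned to the PSD epoch grid (see
    :func:`align_behavior`). With ``scheme='adaptive'`` the SFFS channel
    search runs on the training blocks of each fold only.
    """
    if scheme not in ("standard", "adaptive"):
        raise ParameterError(f"unknown scheme {scheme!r}")
    if len(y.values) != psd.n_epochs:
        raise DataError("behavior series must be aligned to the PSD epoch grid")
    blocks = np.unique(psd.block_ids)
    if blocks.size < 2:
        raise DataError("cross-validation needs at least two blocks")
    for b in blocks:
        if not np.any(psd.block_ids == b):
            raise DataError(f"block {b} has no epochs")

    y_est = np.full(psd.n_epochs, np.nan)
    models, fold_r, sffs_results = [], [], []
    for b in blocks:
        train = psd.block_ids != b
        test = ~train
        train_psd = PSDTimeSeries(psd.logpower[train], psd.freqs,
                                  psd.epoch_times[train], psd.channel_names,
                                  psd.block_ids[train])
        if scheme == "adaptive":
            evaluator = CriterionEvaluator(
                train_psd, y.values[train], candidates=candidates,
                protocol=protocol, variance_threshold=variance_threshold)
            sel = sffs_select(evaluator.candidates, evaluator, k_max=k_max,
                              max_iter=max_iter)
            sffs_results.append(sel)
            channels = list(sel.best_subset)
        else:
            missing = [c for c in standard_channels if c not in psd.channel_names]
            if missing:
                raise ConfigurationError(
                    f"montage lacks required channel(s): {missing}")
            channels = list(standard_channels)

        feats = stack_features(train_psd, channels)
        basis = fit_basis(feats, variance_threshold)
        model = fit_model(feats, basis, y.values[train], metric=y.name,
                          channels=channels)
        models.append(model)
        test_feats = stack_features(psd, channels).X[test]
        pred = model.predict_features(test_feats)
        y_est[test] = pred
        fold_r.append(pearson_r(y.values[test], pred)
                      if np.ptp(pred) > 0 and np.ptp(y.values[test]) > 0 else np.nan)

    overall_r = pearson_r(y.values, y_est)
    nrmse = normalized_rmse(y.values, y_est)
    null = p = None
    if significance:
        null, p = permutation_significance(
            y.values, y_est, times=psd.epoch_times, block_ids=psd.block_ids,
            n_perm=n_perm, window=smoothing_window, alpha=alpha, seed=seed)
    return CVResult(scheme, y.name, list(blocks), models, y.values.copy(),
                    y_est, psd.epoch_times.copy(), psd.block_ids.copy(),
                    fold_r, overall_r, nrmse, null, p, sffs_results,
                    seed if isinstance(seed, int) else None)


@dataclass
class TransferResult:
    """Cross-task application of the per-fold models to the alternate task."""

    per_model_r: list
    mean_r: float
    se_r: float
    rescaled_estimates: list
    skipped: list


def cross_task_transfer(models: list[SpectralRegressionModel],
                        psd_b: PSDTimeSeries, y_b: BehaviorSeries) -> TransferResult:
    """Apply task-A fold models to the full task-B session.

    Each model yields a complete estimate of the task-B behavior; a least
    squares slope+offset maps the estimate onto the new metric's scale
    (this rescale cannot change the magnitude of the correlation, whose
    sign is reported from the unrescaled estimate).
    """
    if len(y_b.values) != psd_b.n_epochs:
        raise DataError("behavior series must be aligned to the PSD epoch grid")
    rs, rescaled, skipped = [], [], []
    for i, model in enumerate(models):
        missing = [c for c in model.channels if c not in psd_b.channel_names]
        if missing:
            warnings.warn(f"model {i} skipped; missing channels {missing}",
                          RuntimeWarning, stacklevel=2)
            skipped.append(i)
            continue
        est = estimate(model, psd_b)
        r = pearson_r(y_b.values, est.values)
        A = np.column_stack([np.ones(est.values.size), est.values])
        coef, *_ = np.linalg.lstsq(A, y_b.values, rcond=None)
        rescaled.append(BehaviorSeries(f"{y_b.name}_transfer", est.times,
                                       coef[0] + coef[1] * est.values,
                                       est.block_ids))
        rs.append(r)
    if not rs:
        raise DataError("no transferred model could be applied")
    rs_arr = np.asarray(rs)
    se = float(rs_arr.std(ddof=1) / np.sqrt(rs_arr.size)) if rs_arr.size > 1 else 0.0
    return TransferResult(rs, float(rs_arr.mean()), se, rescaled, skipped)
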