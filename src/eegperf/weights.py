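"""Per-frequency relative weights of fitted models, with FDR testing.

A fitted model's behavioral estimate is a linear functional of the stacked
log-PSD. Its relative spectral weight at frequency f (for each channel) is

    W(f) = (1 / ||beta||) * sum_i  Xhat(f) * v_i(f) * beta_i

where Xhat(f) is the average training log power at that channel/frequency,
v_i(f) the corresponding entry of the i-th retained eigenvector and beta_i
the regression coefficient. Dividing by the Euclidean norm of beta makes
profiles comparable across models and sessions. Profiles are pooled across
folds and channels, each frequency is tested against zero with a
one-sample t-test, and the 40 p-values are corrected with the
Benjamini-Hochberg step-up procedure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .regression import SpectralRegressionModel


@dataclass
class SpectralWeightProfile:
    """Per-channel, per-frequency relative weights of one fitted model."""

    W: np.ndarray          # (n_channels, n_freqs)
    channels: list[str]
    freqs: np.ndarray
    beta_norm: float


@dataclass
class WeightSummary:
    """Pooled mean profile with per-frequency FDR significance mask."""

    freqs: np.ndarray
    mean_profile: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    n_samples: np.ndarray
    alpha: float


def relative_weights(model: SpectralRegressionModel,
                     mean_psd=None) -> SpectralWeightProfile:
    """Relative weight of each frequency in each of the model's channels.

    ``mean_psd`` is the average training log power per channel/frequency
    (channels x freqs); it defaults to the training means stored in the
    model's eigenbasis (the uncentered average PSD).
    """
    n_ch = len(model.channels)
    d = model.basis.V.shape[0]
    if n_ch == 0 or d % n_ch:
        raise DataError("model channel list inconsistent with basis dimension")
    n_f = d // n_ch
    if mean_psd is None:
        mean_psd = model.basis.means.reshape(n_ch, n_f)
    mean_psd = np.asarray(mean_psd, dtype=float)
    if mean_psd.shape != (n_ch, n_f):
        raise DataError(f"mean_psd must have shape ({n_ch}, {n_f})")
    beta_norm = float(np.linalg.norm(model.beta))
    freqs = np.arange(1, n_f + 1, dtype=float)
    if beta_norm == 0.0:
        warnings.warn("model has zero coefficients; weights are all zero",
                      RuntimeWarning, stacklevel=2)
        return SpectralWeightProfile(np.zeros((n_ch, n_f)), list(model.channels),
                                     freqs, 0.0)
    vb = (model.basis.V @ model.beta).reshape(n_ch, n_f)
    W = mean_psd * vb / beta_norm
    return SpectralWeightProfile(W, list(model.channels), freqs, beta_norm)


def aggregate_and_test(profiles, alpha: float = 0.05) -> WeightSummary:
    """Pool weight profiles across folds/channels and FDR-test each frequency.

    Every channel row of every profile contributes one sample per
    frequency. Frequencies with fewer than two samples are excluded from
    testing (p = NaN, not significant).
    """
    profiles = list(profiles)
    if not profiles:
        raise DataError("need at least one weight profile")
    freqs = profiles[0].freqs
    rows = []
    for p in profiles:
        if not np.array_equal(p.freqs, freqs):
            raise DataError("profiles must share a frequency grid")
        rows.append(np.atleast_2d(p.W))
    pooled = np.vstack(rows)  # (sum of channel rows, n_freqs)

    n_f = pooled.shape[1]
    n_samples = np.full(n_f, pooled.shape[0])
    p_values = np.full(n_f, np.nan)
    testable = n_samples >= 2
    if np.any(testable):
        res = stats.ttest_1samp(pooled, popmean=0.0, axis=0)
        raw_p = np.asarray(res.pvalue, dtype=float)
        # A frequency where every pooled weight is identical (zero spread)
        # yields NaN from the t-test; treat an exactly-zero column as
        # uninformative rather than significant.
        raw_p = np.where(np.isnan(raw_p), 1.0, raw_p)
        p_values[testable] = raw_p[testable]
    significant = np.zeros(n_f, dtype=bool)
    valid = ~np.isnan(p_values)
    if np.any(valid):
        reject, _, _, _ = multipletests(p_values[valid], alpha=alpha,
                                        method="fdr_bh")
        significant[valid] = reject
    return WeightSummary(freqs, pooled.mean(axis=0), p_values, significant,
                         n_samples, alpha)


def band_mean(summary_or_profile, band: tuple[float, float]) -> float:
    """Mean relative weight over an inclusive frequency band."""
    if isinstance(summary_or_profile, WeightSummary):
        freqs, vals = summary_or_profile.freqs, summary_or_profile.mean_profile
    else:
        freqs = summary_or_profile.freqs
        vals = summary_or_profile.W.mean(axis=0)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise DataError(f"no frequencies inside band {band}")
    return float(np.mean(vals[sel]))
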