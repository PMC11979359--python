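"""Head-motion fingerprinting: 12 FWD metrics and cohort-level PCA.

Each framewise-displacement (FWD) trace is summarized by 12 metrics:
log max, mean, median, SD, skewness; two wavelet-band variance ratios
(mid-frequency scales 3-5 over total, and log high (scales 1-2) over low
(scale 6)); maximum-likelihood gamma shape A and log scale B; and three
Hurst-exponent estimates for fractional Brownian motion:

* ``hurst_1`` -- discrete second-derivative variance-ratio estimator,
  ``H = 0.5 * log2(var(d2) / var(d1))`` with ``d1`` the second difference
  and ``d2`` its lag-2 dilation;
* ``hurst_2`` -- the wavelet-domain analog: a zero-mean (db2) wavelet filter
  and its dyadic dilation replace the second-difference filter, with the
  same ``2**(2H)`` variance-ratio law;
* ``hurst_3`` -- slope of log2 per-scale MODWT detail variance of the
  increments on scale index: fGn variance decays as ``2**(-j*(2-2H))``, so
  ``H = 1 + slope/2``.

Per-subject metric means across the six sequences are z-scored and submitted
to a cohort PCA (:class:`MotionPCA`); the top five component scores serve as
between-subject motion covariates throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic_data import MotionTrace
from .wavelet import wavelet_variances

__all__ = [
    "METRIC_NAMES",
    "MotionMetricVector",
    "MotionComponentScores",
    "fwd_metrics",
    "hurst_estimates",
    "cohort_motion_pca",
    "MotionPCA",
    "cohort_motion_metrics",
]

METRIC_NAMES = [
    "max_fwd_log",
    "mean_fwd",
    "median_fwd",
    "sd_fwd",
    "skew_fwd",
    "midfreq_ratio",
    "hf_lf_ratio_log",
    "gamma_shape_A",
    "gamma_scale_B_log",
    "hurst_1",
    "hurst_2",
    "hurst_3",
]


@dataclass
class MotionMetricVector:
    values: dict[str, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in METRIC_NAMES])


def _second_diff(x: np.ndarray, lag: int) -> np.ndarray:
    return x[2 * lag :] - 2 * x[lag:-lag] + x[: -2 * lag]


def hurst_estimates(series: np.ndarray, min_length: int = 128) -> tuple[float, float, float]:
    """Three Hurst-index estimates for an fBm-like series; see module docs."""
    x = np.asarray(series, float)
    if x.size < min_length:
        raise ValueError(f"need at least {min_length} points for Hurst estimation")
    if np.ptp(x) == 0:
        raise ValueError("constant series: Hurst undefined")
    # fluctuation-free (smooth monotone) input pins the estimators at the
    # persistent boundary H = 1
    tiny = 1e-18 * np.var(x)
    d1 = _second_diff(x, 1)
    d2 = _second_diff(x, 2)
    v1, v2 = np.mean(d1**2), np.mean(d2**2)
    h1 = 0.5 * np.log2(v2 / v1) if v1 > tiny and v2 > tiny else 1.0
    # wavelet-domain analog: a zero-mean wavelet filter and its 2x dilation
    # play the role of the second difference; variance ratio is 2**(2H)
    import pywt

    hi = np.asarray(pywt.Wavelet("db2").dec_hi, float)
    hi2 = np.zeros(2 * hi.size - 1)
    hi2[::2] = hi
    w1 = np.convolve(x, hi, mode="valid")
    w2 = np.convolve(x, hi2, mode="valid")
    v1w, v2w = np.mean(w1**2), np.mean(w2**2)
    h2 = 0.5 * np.log2(v2w / v1w) if v1w > tiny and v2w > tiny else 1.0
    # log-regression of per-scale wavelet variance of the increments:
    # fGn wavelet variance scales as 2**(-j*(2 - 2H)), so H = 1 + slope/2
    inc = np.diff(x)
    levels = min(6, int(np.log2(inc.size)) - 2)
    wv = wavelet_variances(inc, levels=levels)
    j = np.arange(1, levels + 1)
    good = wv > tiny
    if good.sum() < 2:
        h3 = 1.0
    else:
        slope = np.polyfit(j[good], np.log2(wv[good]), 1)[0]
        h3 = 1.0 + slope / 2.0
    return float(h1), float(h2), float(h3)


def fwd_metrics(fwd: np.ndarray, min_length: int = 64) -> MotionMetricVector:
    """All 12 motion metrics of one FWD trace (nonnegative, length >= 64)."""
    f = np.asarray(fwd, float)
    if f.size < min_length:
        raise ValueError(f"FWD series too short ({f.size} < {min_length})")
    if np.any(f < 0):
        raise ValueError("FWD must be nonnegative")
    if np.ptp(f) == 0:
        raise ValueError("constant FWD series: skewness and Hurst undefined")
    levels = min(6, int(np.log2(f.size)))
    wv = wavelet_variances(f, levels=levels)
    total = wv.sum()
    mid = wv[2:5].sum() if levels >= 5 else wv[2:].sum()
    hf = wv[:2].sum()
    lf = wv[levels - 1]
    pos = f[f > 0]
    f_gamma = np.where(f > 0, f, 0.5 * pos.min())
    shape, _, scale = stats.gamma.fit(f_gamma, floc=0)
    h1, h2, h3 = hurst_estimates(f, min_length=min_length)
    vals = {
        "max_fwd_log": float(np.log(f.max())),
        "mean_fwd": float(f.mean()),
        "median_fwd": float(np.median(f)),
        "sd_fwd": float(f.std(ddof=1)),
        "skew_fwd": float(stats.skew(f, bias=False)),
        "midfreq_ratio": float(mid / total),
        "hf_lf_ratio_log": float(np.log(hf / lf)),
        "gamma_shape_A": float(shape),
        "gamma_scale_B_log": float(np.log(scale)),
        "hurst_1": h1,
        "hurst_2": h2,
        "hurst_3": h3,
    }
    return MotionMetricVector(values=vals)


def cohort_motion_metrics(motion: list[list[MotionTrace]], subject_ids=None) -> pd.DataFrame:
    """Subject x 12 table of metric means across sequences."""
    rows = []
    for traces in motion:
        per_seq = np.stack([fwd_metrics(t.fwd).as_array() for t in traces])
        rows.append(per_seq.mean(axis=0))
    idx = subject_ids if subject_ids is not None else [f"S{i:04d}" for i in range(len(rows))]
    return pd.DataFrame(rows, columns=METRIC_NAMES, index=idx)


@dataclass
class MotionComponentScores:
    scores: np.ndarray               # subjects x k
    loadings: np.ndarray             # 12 x k, unit-norm columns
    eigenvalue_fractions: np.ndarray


class MotionPCA(BaseEstimator, TransformerMixin):
    """PCA of z-scored subject x 12 motion-metric means (top ``n_components``).

    Deterministic sign convention: the largest-magnitude loading of each
    component is positive.  ``transform`` returns component scores.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = self._validate(X)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        self.sd_[self.sd_ == 0] = 1.0
        Z = (X - self.mean_) / self.sd_
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        k = self.n_components
        load = Vt[:k].T
        flip = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        self.loadings_ = load * flip
        self.eigenvalue_fractions_ = (s[:k] ** 2) / np.sum(s**2)
        return self

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        Z = (X - self.mean_) / self.sd_
        return Z @ self.loadings_

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("expected a subject x metric matrix")
        if not np.all(np.isfinite(X)):
            bad = np.unique(np.nonzero(~np.isfinite(X))[0])
            raise ValueError(f"missing/non-finite metrics for subject rows {bad.tolist()}")
        return X


def cohort_motion_pca(metric_means: pd.DataFrame | np.ndarray, k: int = 5) -> MotionComponentScores:
    """Cohort motion PCA (>= 12 subjects required); see :class:`MotionPCA`."""
    X = metric_means.values if isinstance(metric_means, pd.DataFrame) else np.asarray(metric_means, float)
    if X.shape[0] < 12:
        raise ValueError("need at least 12 subjects for a stable motion PCA")
    est = MotionPCA(n_components=k).fit(X)
    return MotionComponentScores(
        scores=est.transform(X),
        loadings=est.loadings_,
        eigenvalue_fractions=est.eigenvalue_fractions_,
    )
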