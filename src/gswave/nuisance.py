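"""Two-stage component-based nuisance correction (modified CompCor).

Stage 1 isolates transient artifacts ("spikes"): principal components of a
high-variance noise pool whose series are heavy-tailed (raw kurtosis > 4.5)
and contain extreme excursions (|z| > 4.5) contribute spike-only regressors
(the |z| > 3 entries of the component, zero elsewhere), combined with
one-frame regressors for motion spikes (> 1 mm high-pass-detrended framewise
displacement).  The joint spike set is PCA-reduced to remove collinearity and
regressed out together with any task design.

Stage 2 is standard CompCor: the top seven principal components of the
spike-cleaned noise pool plus their first differences (14 regressors),
combined with seven PCA-compressed motion regressors derived from the six
rigid-body parameters + detrended FWD (-> 14 basic/sqrt-abs series -> + first
and second derivatives = 42 -> z-score -> PCA -> top 7).

``NuisanceRegressor`` wraps the final regression as a scikit-learn style
transformer: ``fit`` assembles/validates the design, ``transform`` returns
residuals orthogonal to every regressor column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._filters import dct_highpass
from .synthetic_data import MotionTrace

__all__ = [
    "SpikeRegressorSet",
    "NuisanceModel",
    "build_noise_pool",
    "detect_spike_regressors",
    "compcor_components",
    "motion_regressors",
    "regress_nuisance",
    "NuisanceRegressor",
]

KURTOSIS_THRESHOLD = 4.5      # raw kurtosis (Gaussian = 3)
Z_COMPONENT_THRESHOLD = 4.5   # excursion needed to flag a component
Z_SPIKE_KEEP = 3.0            # entries retained in a spike series
FWD_SPIKE_MM = 1.0
N_POOL_COMPONENTS = 30
N_COMPCOR = 7


@dataclass
class SpikeRegressorSet:
    """Time x k spike regressors, nonzero only at spike frames."""

    spike_series: np.ndarray
    source: list[str] = field(default_factory=list)  # "component" or "motion" per column
    pca_reduced: bool = False

    @property
    def n_regressors(self) -> int:
        return 0 if self.spike_series.size == 0 else self.spike_series.shape[1]


@dataclass
class NuisanceModel:
    spike_regressors: SpikeRegressorSet
    compcor_regressors: np.ndarray   # time x 14
    motion_regressors: np.ndarray    # time x 7
    task_design: np.ndarray | None = None


def build_noise_pool(
    sd_map: np.ndarray, exclusion_labels: np.ndarray | None = None, frac: float = 0.02
) -> np.ndarray:
    """Indices of the top-``frac`` highest-SD candidate series, exclusions removed.

    ``exclusion_labels`` marks series that must not enter the pool (the
    anatomical analog: amygdala/striatum voxels inside a white-matter mask).
    At least one index is always returned.
    """
    sd_map = np.asarray(sd_map, float)
    n = sd_map.size
    if n < 50:
        raise ValueError(f"need at least 50 candidate series, got {n}")
    mask = np.ones(n, dtype=bool)
    if exclusion_labels is not None:
        mask &= ~np.asarray(exclusion_labels, bool)
    if not mask.any():
        raise ValueError("all candidate series are excluded")
    k = max(int(np.floor(frac * n)), 1)
    candidates = np.flatnonzero(mask)
    order = candidates[np.argsort(sd_map[candidates], kind="stable")[::-1]]
    return np.sort(order[:k])


def _highpass(x: np.ndarray, cutoff_hz: float, tr: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass along the first axis."""
    nyq = 0.5 / tr
    wn = min(cutoff_hz / nyq, 0.99)
    sos = sp_signal.butter(order, wn, btype="highpass", output="sos")
    return sp_signal.sosfiltfilt(sos, x, axis=0)


def detrended_fwd(fwd: np.ndarray, tr: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """High-pass-detrended FWD: the trace minus its low-pass (slow) trend.

    Subtracting the zero-phase Butterworth low-pass estimate (rather than
    applying a high-pass filter directly) preserves the amplitude of
    single-frame spikes against the > 1 mm threshold.
    """
    x = np.asarray(fwd, float)
    nyq = 0.5 / tr
    sos = sp_signal.butter(4, min(cutoff_hz / nyq, 0.99), btype="lowpass", output="sos")
    return x - sp_signal.sosfiltfilt(sos, x, axis=0)


def detect_spike_regressors(
    noise_series: np.ndarray,
    fwd: MotionTrace | np.ndarray | None = None,
    tr: float = 1.5,
    n_components: int = N_POOL_COMPONENTS,
    detrend_cutoff_hz: float = 0.01,
) -> SpikeRegressorSet:
    """Spike regressors from noise-pool components and motion spikes.

    PCA of the noise pool -> top ``n_components`` component series; those with
    raw kurtosis > 4.5 AND any |z| > 4.5 contribute a spike series keeping
    only the |z| > 3 entries.  Frames with detrended FWD > 1 mm add one-frame
    motion spike regressors.  The joint set is PCA-reduced (eigenvalues
    > 1e-8 x trace retained).  An empty set is a valid result.
    """
    X = np.asarray(noise_series, float)
    T = X.shape[0]
    Xc = X - X.mean(axis=0)
    k = min(n_components, min(Xc.shape) - 1)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    comps = U[:, :k] * s[:k]
    series, sources = [], []
    for i in range(comps.shape[1]):
        c = comps[:, i]
        sd = c.std(ddof=1)
        if sd == 0:
            continue
        z = (c - c.mean()) / sd
        if stats.kurtosis(z, fisher=False) > KURTOSIS_THRESHOLD and np.max(np.abs(z)) > Z_COMPONENT_THRESHOLD:
            spike = np.where(np.abs(z) > Z_SPIKE_KEEP, z, 0.0)
            if np.any(spike != 0):
                series.append(spike)
                sources.append("component")
    if fwd is not None:
        f = fwd.fwd if isinstance(fwd, MotionTrace) else np.asarray(fwd, float)
        if f.size == T - 1:  # length T-1 convention: frame t reflects motion t-1 -> t
            f = np.concatenate([[0.0], f])
        det = detrended_fwd(f, tr, detrend_cutoff_hz)
        for t in np.flatnonzero(det > FWD_SPIKE_MM):
            one = np.zeros(T)
            one[t] = 1.0
            series.append(one)
            sources.append("motion")
    if not series:
        return SpikeRegressorSet(spike_series=np.empty((T, 0)), source=[], pca_reduced=False)
    S = np.column_stack(series)
    # joint PCA (uncentered SVD) to remove exact collinearity among spike
    # series; no centering so the regressors stay zero off-spike
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    keep = sv**2 > 1e-8 * np.sum(sv**2)
    reduced = U[:, keep] * sv[keep]
    return SpikeRegressorSet(spike_series=reduced, source=sources, pca_reduced=True)


def compcor_components(noise_series: np.ndarray, n_components: int = N_COMPCOR) -> np.ndarray:
    """Top-7 noise-pool principal components + first differences (14 columns).

    Derivatives are first differences, zero-padded at the first element.
    Raises if the pool rank is below ``n_components``.
    """
    X = np.asarray(noise_series, float)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if rank < n_components:
        raise ValueError(
            f"noise pool rank {rank} is below the {n_components} requested CompCor components"
        )
    comps = U[:, :n_components] * s[:n_components]
    deriv = np.vstack([np.zeros((1, n_components)), np.diff(comps, axis=0)])
    return np.hstack([comps, deriv])


def motion_regressors(
    trace: MotionTrace, tr: float = 1.5, stopband_hz: float = 0.001, n_components: int = 7
) -> np.ndarray:
    """Seven orthogonal motion principal-component series.

    Pipeline: [6 rigid-body params + detrended FWD] -> high-pass (stopband
    0.001 Hz) -> 14 series (basic + sqrt(|.|)) -> + first and second
    differences (42 series) -> z-score -> PCA -> top-7 scores.
    """
    params = np.asarray(trace.params, float)
    T = params.shape[0]
    f = np.concatenate([[0.0], np.asarray(trace.fwd, float)]) if trace.fwd.size == T - 1 else trace.fwd
    base = np.column_stack([params, detrended_fwd(f, tr)])
    if np.allclose(base, 0):
        raise ValueError("all-zero motion trace: motion PCA is degenerate")
    # "remove very low frequencies": DCT projection below the stopband
    # (recursive filters are ill-conditioned at these cutoffs/lengths)
    base = dct_highpass(base, tr, cutoff_seconds=1.0 / stopband_hz)
    mat14 = np.hstack([base, np.sqrt(np.abs(base))])

    def _d(x):
        return np.vstack([np.zeros((1, x.shape[1])), np.diff(x, axis=0)])

    mat42 = np.hstack([mat14, _d(mat14), _d(_d(mat14))])
    assert mat42.shape[1] == 42
    sd = mat42.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (mat42 - mat42.mean(axis=0)) / sd
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    return U[:, :n_components] * s[:n_components]


def _ols_residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of Y on [1, X]; collinear columns handled by least squares."""
    design = np.column_stack([np.ones(Y.shape[0]), X]) if X.size else np.ones((Y.shape[0], 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"rank-deficient nuisance design ({rank}/{design.shape[1]}); collinear "
            "columns absorbed by least squares",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ beta


class NuisanceRegressor(BaseEstimator, TransformerMixin):
    """Regress a :class:`NuisanceModel` out of a time x region matrix.

    Two-stage: spike + task regressors first, then the full joint design
    (spikes, task, CompCor, motion) so the residuals are orthogonal to every
    regressor column.  scikit-learn transformer interface: ``fit(X)`` checks
    alignment, ``transform(X)`` returns residuals.
    """

    def __init__(self, model: NuisanceModel):
        self.model = model

    def _designs(self, T: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.model
        parts1 = []
        if m.spike_regressors.n_regressors:
            parts1.append(m.spike_regressors.spike_series)
        if m.task_design is not None:
            parts1.append(np.asarray(m.task_design, float))
        for part in parts1 + [m.compcor_regressors, m.motion_regressors]:
            if part.shape[0] != T:
                raise ValueError(
                    f"regressor rows ({part.shape[0]}) must equal data rows ({T})"
                )
        stage1 = np.column_stack(parts1) if parts1 else np.empty((T, 0))
        stage2 = np.column_stack([stage1, m.compcor_regressors, m.motion_regressors])
        return stage1, stage2

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        stage1, stage2 = self._designs(X.shape[0])
        self.n_regressors_ = stage2.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        stage1, stage2 = self._designs(X.shape[0])
        resid = _ols_residuals(X, stage1) if stage1.size else X
        return _ols_residuals(resid, stage2)


def regress_nuisance(data: np.ndarray, model: NuisanceModel) -> np.ndarray:
    """Functional wrapper around :class:`NuisanceRegressor`."""
    return NuisanceRegressor(model).fit(data).transform(data)


def clean_sequence(
    data: np.ndarray,
    noise_pool: np.ndarray,
    trace: MotionTrace,
    tr: float = 1.5,
    task_design: np.ndarray | None = None,
) -> tuple[np.ndarray, NuisanceModel]:
    """End-to-end per-sequence cleaning: spikes -> task -> CompCor + motion."""
    spikes = detect_spike_regressors(noise_pool, trace, tr=tr)
    pool_clean = (
        _ols_residuals(noise_pool, spikes.spike_series)
        if spikes.n_regressors
        else noise_pool
    )
    model = NuisanceModel(
        spike_regressors=spikes,
        compcor_regressors=compcor_components(pool_clean),
        motion_regressors=motion_regressors(trace, tr=tr),
        task_design=task_design,
    )
    return regress_nuisance(data, model), model
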