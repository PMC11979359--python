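"""Parcel-level global-signal topography.

Each region's association with the gray-matter global series is the slope
t-statistic of a simple regression (region on GS + intercept) after a 128-s
discrete-cosine high-pass of both series, mapped to a z-statistic through
the normal quantile of the t CDF at the fitted degrees of freedom (capped at
|z| = 8 for near-perfect fits).  Group and acquisition-order effects on
these z-maps are tested with covariate-adjusted regression and max-|t|
permutation family-wise error (FWE) control across regions -- the
parcel-level analog of voxelwise cluster-corrected inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._filters import dct_highpass
from .gs_metrics import order_contrast_weights

__all__ = [
    "TopographyMap",
    "region_gs_association",
    "sequence_topography",
    "group_topography_test",
    "order_topography_trend",
]

Z_CAP = 8.0


def region_gs_association(
    region: np.ndarray, gs: np.ndarray, tr: float = 1.5, highpass_seconds: float = 128.0
) -> float:
    """z-statistic of the region-on-GS regression slope (128-s high-passed)."""
    r = dct_highpass(np.asarray(region, float), tr, highpass_seconds)
    g = dct_highpass(np.asarray(gs, float), tr, highpass_seconds)
    if r.std() == 0 or g.std() == 0:
        raise ValueError("zero-variance input to region-GS association")
    T = r.size
    X = np.column_stack([np.ones(T), g])
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    resid = r - X @ beta
    dof = T - 2
    se = np.sqrt(np.sum(resid**2) / dof / np.sum((g - g.mean()) ** 2))
    t = beta[1] / se
    z = stats.norm.ppf(stats.t.cdf(t, dof))
    if not np.isfinite(z) or abs(z) > Z_CAP:
        z = np.sign(t) * Z_CAP
    return float(z)


@dataclass
class TopographyMap:
    """z-maps: subjects x sequences x regions."""

    z: np.ndarray
    gs_mode: str = "standard"
    highpass_seconds: float = 128.0


def sequence_topography(
    cohort_data: dict, gs_mode: str = "standard", tr: float = 1.5
) -> TopographyMap:
    """Per subject x sequence x region z-maps from cleaned matrices.

    ``cohort_data``: subject id -> list of dicts with ``data`` (time x
    region).  ``gs_mode`` selects the standard (region-mean) or weighted
    (z-scored-region mean) global series.
    """
    from .gs_metrics import gs_timeseries

    sids = list(cohort_data)
    n_seq = len(cohort_data[sids[0]])
    n_reg = cohort_data[sids[0]][0]["data"].shape[1]
    z = np.empty((len(sids), n_seq, n_reg))
    for i, sid in enumerate(sids):
        for q, seq in enumerate(cohort_data[sid]):
            X = np.asarray(seq["data"], float)
            g = gs_timeseries(X, weighted=(gs_mode == "weighted"))
            for r in range(n_reg):
                z[i, q, r] = region_gs_association(X[:, r], g, tr=tr)
    return TopographyMap(z=z, gs_mode=gs_mode)


def _region_tstats(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """t of the column-1 coefficient for every region column of Y."""
    pinv_xx = np.linalg.inv(X.T @ X)
    beta = pinv_xx @ X.T @ Y
    resid = Y - X @ beta
    dof = Y.shape[0] - X.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(sigma2 * pinv_xx[1, 1])
    se[se == 0] = np.inf
    return beta[1] / se


def group_topography_test(
    maps: TopographyMap,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Max-|t| permutation FWE test of a group effect on mean z-maps.

    Sequence-mean z-maps are regressed on group + covariates; group labels
    are permuted (covariates stay attached to subjects) and the null
    distribution of the maximum |t| across regions calibrates the corrected
    threshold.  Returns per-region t, FWE p-values and the detected set.
    """
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very low for FWE control", stacklevel=2)
    rng = np.random.default_rng(seed)
    Y = maps.z.mean(axis=1)
    g = np.asarray(group, float)
    cov = [] if covariates is None else [np.asarray(covariates, float)]
    X = np.column_stack([np.ones_like(g), g] + cov)
    t_obs = _region_tstats(Y, X)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        Xp = X.copy()
        Xp[:, 1] = rng.permutation(g)
        max_null[b] = np.max(np.abs(_region_tstats(Y, Xp)))
    p_fwe = (1 + np.sum(max_null[None, :] >= np.abs(t_obs)[:, None], axis=1)) / (n_perm + 1)
    return {
        "t": t_obs,
        "p_fwe": p_fwe,
        "significant": np.flatnonzero(p_fwe < alpha),
        "max_null": max_null,
    }


def order_topography_trend(
    maps: TopographyMap,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    sign_convention: str = "increase_positive",
) -> dict:
    """Sign-flip max-|t| test of the linear order trend of the z-maps.

    Per subject and region, the linear acquisition-order contrast of the
    sequence z-maps; one-sample inference by random sign flips of subjects'
    contrast maps with max-statistic FWE correction.
    """
    rng = np.random.default_rng(seed)
    n_sub, n_seq, n_reg = maps.z.shape
    w = order_contrast_weights(n_seq, sign_convention)
    con = np.tensordot(maps.z, w, axes=(1, 0))  # subjects x regions

    def one_sample_t(C):
        m = C.mean(axis=0)
        se = C.std(axis=0, ddof=1) / np.sqrt(C.shape[0])
        se[se == 0] = np.inf
        return m / se

    t_obs = one_sample_t(con)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_sub)
        max_null[b] = np.max(np.abs(one_sample_t(con * flips[:, None])))
    p_fwe = (1 + np.sum(max_null[None, :] >= np.abs(t_obs)[:, None], axis=1)) / (n_perm + 1)
    return {
        "contrast": con,
        "t": t_obs,
        "p_fwe": p_fwe,
        "significant": np.flatnonzero(p_fwe < alpha),
    }
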