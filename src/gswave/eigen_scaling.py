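"""Eigenvalue power-law scaling of regional time-series PCA spectra.

For each sequence, PCA of the time x region matrix yields a decreasing
eigenvalue spectrum modeled as

    EVM = a * (#EV)**b + c

where ``a`` captures the overall scaling (amplitude) of the spectrum, ``b``
its decay rate ("complexity": many comparable sources vs one dominant
mode), and ``c`` an offset.  Amplitude differences between groups move ``a``
(and ``c``) but not ``b``; z-scoring each region before the PCA ("scaled"
mode) removes pure amplitude effects, so a group difference that survives
scaling is not a scaling phenomenon.  ``a`` is log-transformed for
inference.

:class:`PowerLawEigenModel` performs the nonlinear least-squares fit with
multi-start initialization (b0 in {-0.5, -1, -2}); it is deterministic given
its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .wavelet import band_component

__all__ = [
    "EigenFit",
    "eigen_spectrum",
    "fit_power_law",
    "PowerLawEigenModel",
    "subject_eigen_fits",
    "compare_eigen_params",
]


@dataclass
class EigenFit:
    a: float
    b: float
    c: float
    r_squared: float
    scaled: bool = False
    frequency_band: str = "all"


def eigen_spectrum(data: np.ndarray, scaled: bool = False) -> np.ndarray:
    """Nonincreasing eigenvalues of the regional covariance of ``data``.

    ``scaled`` z-scores each region first (correlation-matrix PCA; the
    eigenvalues then sum to the region count).  Constant regions are dropped
    with a warning in scaled mode.
    """
    X = np.asarray(data, float)
    if X.ndim != 2 or X.shape[1] < 4:
        raise ValueError("need a time x region matrix with >= 4 regions")
    X = X - X.mean(axis=0)
    if scaled:
        sd = X.std(axis=0, ddof=1)
        good = sd > 0
        if not good.all():
            import warnings

            warnings.warn(f"dropping {int((~good).sum())} constant region(s) in scaled mode", stacklevel=2)
        X = X[:, good] / sd[good]
    s = np.linalg.svd(X, compute_uv=False)
    ev = s**2 / (X.shape[0] - 1)
    return ev


def _power_law(n, a, b, c):
    return a * np.power(n, b) + c


class PowerLawEigenModel(BaseEstimator):
    """Fit EVM = a * #EV**b + c to an eigenvalue spectrum.

    scikit-learn estimator interface: ``fit(eigenvalues)`` sets ``a_``,
    ``b_``, ``c_`` and ``r_squared_``.  The fit uses the leading
    ``max_rank`` eigenvalues and tries each starting decay in ``b_starts``,
    keeping the lowest residual solution.
    """

    def __init__(self, max_rank: int = 100, b_starts: tuple[float, ...] = (-0.5, -1.0, -2.0)):
        self.max_rank = max_rank
        self.b_starts = b_starts

    def fit(self, eigenvalues, y=None):
        ev = np.asarray(eigenvalues, float).ravel()
        if ev.size < 10:
            raise ValueError("need at least 10 eigenvalues for a power-law fit")
        ev = ev[: self.max_rank]
        n = np.arange(1, ev.size + 1, dtype=float)
        best = None
        errors = []
        for b0 in self.b_starts:
            a0 = max(ev[0] - ev[-1], 1e-12)
            try:
                popt, _ = curve_fit(
                    _power_law, n, ev, p0=[a0, b0, ev[-1]], maxfev=20000
                )
                resid = ev - _power_law(n, *popt)
                sse = float(np.sum(resid**2))
                if best is None or sse < best[1]:
                    best = (popt, sse)
            except RuntimeError as err:  # non-convergence for this start
                errors.append(f"b0={b0}: {err}")
        if best is None:
            raise RuntimeError("power-law fit failed for all starts: " + "; ".join(errors))
        popt, sse = best
        sst = float(np.sum((ev - ev.mean()) ** 2))
        self.a_, self.b_, self.c_ = (float(v) for v in popt)
        self.r_squared_ = 1.0 - sse / sst if sst > 0 else 1.0
        self.n_eigenvalues_ = ev.size
        return self


def fit_power_law(eigenvalues, scaled: bool = False, frequency_band: str = "all") -> EigenFit:
    est = PowerLawEigenModel().fit(eigenvalues)
    return EigenFit(
        a=est.a_, b=est.b_, c=est.c_, r_squared=est.r_squared_,
        scaled=scaled, frequency_band=frequency_band,
    )


def subject_eigen_fits(
    sequences: list[np.ndarray],
    scaled: bool = False,
    frequency_band: str = "all",
    lowfreq_scales: tuple[int, ...] = (4, 5, 6),
    levels: int = 6,
    band_aggregation: str = "average",
) -> pd.DataFrame:
    """Power-law fits per sequence x wavelet band ("fit per band, then average").

    Each regional series is split into its per-scale wavelet components (the
    scale-``levels`` smooth is folded into the deepest band); the eigenvalue
    spectrum and power-law fit are computed separately for every band in the
    set (``all`` -> scales 1..levels, ``low`` -> ``lowfreq_scales``), and the
    caller averages parameters across rows.  In scaled mode each region's
    band component is z-scored before the PCA, so a pure amplitude scaling
    of a band cancels exactly.
    """
    from .wavelet import modwt_decompose

    band_set = tuple(range(1, levels + 1)) if frequency_band == "all" else tuple(lowfreq_scales)
    rows = []
    for q, X in enumerate(sequences):
        X = np.asarray(X, float)
        dec = modwt_decompose(X.T, levels=levels)
        D, S = dec.mra()
        comps = {j: D[j - 1] + (S if j == levels else 0.0) for j in band_set}
        if band_aggregation == "concatenate":
            stacked = np.concatenate([comps[j] for j in band_set], axis=-1).T
            fit = fit_power_law(eigen_spectrum(stacked, scaled=scaled), scaled, frequency_band)
            rows.append(
                {"sequence": q + 1, "scale": 0, "a": fit.a, "b": fit.b, "c": fit.c,
                 "r_squared": fit.r_squared}
            )
            continue
        if band_aggregation != "average":
            raise ValueError(f"unknown band_aggregation {band_aggregation!r}")
        for j in band_set:
            fit = fit_power_law(eigen_spectrum(comps[j].T, scaled=scaled), scaled, frequency_band)
            rows.append(
                {
                    "sequence": q + 1,
                    "scale": j,
                    "a": fit.a,
                    "b": fit.b,
                    "c": fit.c,
                    "r_squared": fit.r_squared,
                }
            )
    return pd.DataFrame(rows)


def compare_eigen_params(
    fits: pd.DataFrame,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Group tests on subject-mean log(a), b, c.

    ``fits`` must have one row per subject with columns a, b, c (already
    averaged across sequences/bands).  OLS of each parameter on group plus
    optional covariates; returns t and p per parameter.
    """
    g = np.asarray(group, float)
    if min((g == v).sum() for v in np.unique(g)) < 3:
        raise ValueError("each group needs at least 3 subjects")
    params = {
        "log_a": np.log(np.clip(fits["a"].values, 1e-12, None)),
        "b": fits["b"].values,
        "c": fits["c"].values,
    }
    design = [np.ones_like(g), g]
    if covariates is not None:
        C = np.asarray(covariates, float)
        design.append(C if C.ndim == 2 else C[:, None])
    X = np.column_stack(design)
    pinv_xx = np.linalg.inv(X.T @ X)
    rows = []
    for name, y in params.items():
        beta = pinv_xx @ X.T @ y
        resid = y - X @ beta
        dof = len(y) - X.shape[1]
        se = np.sqrt(np.sum(resid**2) / dof * pinv_xx[1, 1])
        t = beta[1] / se
        rows.append({"parameter": name, "t": float(t), "p": float(2 * stats.t.sf(abs(t), dof)), "df": dof})
    return pd.DataFrame(rows)
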