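"""Feature selection and permutation-tested PLS brain/behavior mapping.

Thirty brain measures are chosen per analysis by one of four methods, always
after excluding candidates with |skewness| > 1:

* ``correlation`` -- largest maximum absolute correlation with any of the 26
  questionnaire scales (demographics excluded);
* ``icc`` -- largest between-sequence ICC(3,1);
* ``combined`` -- largest sum of the z-scored correlation and ICC scores;
* ``dynamic`` -- largest spread of behavior correlations across the six
  sequences; the selected feature value is the FC change between the
  sequences attaining the extreme correlations.

The PLS variant is the symmetric PLS-SVD of the column-standardized
cross-covariance ``X'Y/(n-1)``: singular vectors are the X/Y saliences,
component "strength" is the correlation of the paired X and Y scores.
Significance is by permutation of the rows of Y (10 components, default
5000 permutations, ``p = (1 + #{perm >= obs}) / (n_perm + 1)``).  Train/test
replication is assessed by sign-aligned salience correlations
(:func:`correspondence`) and by PCA loading correspondence.

Selections made on a training cohort are frozen before being applied to a
test cohort; selecting on correlations inflates training-sample p-values
(leakage), which the frozen test-cohort evaluation avoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .pipeline import bonferroni

__all__ = [
    "FeatureSelection",
    "PLSResult",
    "CorrespondenceReport",
    "select_features",
    "pls_fit",
    "PLSPermutation",
    "pls_permutation",
    "correspondence",
    "pca_correspondence",
    "replication_thresholds",
]

SKEW_LIMIT = 1.0


@dataclass
class FeatureSelection:
    method: str
    indices: np.ndarray
    skew_excluded: np.ndarray
    fitted_on: str = "train"
    dynamic_hi_lo: np.ndarray | None = None  # (k, 2) sequence indices for dynamic method

    def values(self, candidates: np.ndarray, per_sequence: np.ndarray | None = None) -> np.ndarray:
        """Feature matrix for a (possibly new) cohort with frozen indices."""
        if self.method == "dynamic":
            if per_sequence is None:
                raise ValueError("dynamic selection needs per-sequence measures")
            hi = self.dynamic_hi_lo[:, 0]
            lo = self.dynamic_hi_lo[:, 1]
            cols = [per_sequence[:, hi[i], self.indices[i]] - per_sequence[:, lo[i], self.indices[i]]
                    for i in range(self.indices.size)]
            return np.column_stack(cols)
        return candidates[:, self.indices]


def _max_abs_behavior_corr(candidates: np.ndarray, behavior: np.ndarray) -> np.ndarray:
    """Max |corr| of each candidate column with any behavior column."""
    Xc = candidates - candidates.mean(axis=0)
    Yc = behavior - behavior.mean(axis=0)
    xs = Xc.std(axis=0, ddof=1)
    ys = Yc.std(axis=0, ddof=1)
    xs[xs == 0] = np.inf
    ys[ys == 0] = np.inf
    C = (Xc / xs).T @ (Yc / ys) / (candidates.shape[0] - 1)
    return np.max(np.abs(C), axis=1)


def select_features(
    candidates: np.ndarray,
    behavior: np.ndarray,
    method: str = "correlation",
    k: int = 30,
    iccs: np.ndarray | None = None,
    per_sequence: np.ndarray | None = None,
    fitted_on: str = "train",
) -> FeatureSelection:
    """Pick ``k`` measure indices by the named method (skew filter first).

    ``candidates``: subjects x measures (sequence means); ``behavior``:
    subjects x 26 scales; ``iccs``: per-measure ICC(3,1) (icc/combined
    methods); ``per_sequence``: subjects x sequences x measures (dynamic).
    Ties break by measure id (stable sort).
    """
    X = np.asarray(candidates, float)
    n_feat = X.shape[1]
    skews = stats.skew(X, axis=0, bias=False)
    eligible = np.abs(skews) <= SKEW_LIMIT
    excluded = np.flatnonzero(~eligible)
    if method == "correlation":
        score = _max_abs_behavior_corr(X, behavior)
    elif method == "icc":
        if iccs is None:
            raise ValueError("icc method requires per-measure ICCs")
        score = np.asarray(iccs, float).copy()
    elif method == "combined":
        if iccs is None:
            raise ValueError("combined method requires per-measure ICCs")
        c = _max_abs_behavior_corr(X, behavior)
        z = lambda v: (v - v.mean()) / (v.std(ddof=1) or 1.0)  # noqa: E731
        score = z(c) + z(np.asarray(iccs, float))
    elif method == "dynamic":
        if per_sequence is None:
            raise ValueError("dynamic method requires per-sequence measures")
        P = np.asarray(per_sequence, float)
        n_sub, n_seq, _ = P.shape
        B = np.asarray(behavior, float)
        corr = np.empty((n_seq, n_feat, B.shape[1]))
        Bc = (B - B.mean(axis=0)) / B.std(axis=0, ddof=1)
        for q in range(n_seq):
            Q = P[:, q, :]
            Qc = Q - Q.mean(axis=0)
            qs = Qc.std(axis=0, ddof=1)
            qs[qs == 0] = np.inf
            corr[q] = (Qc / qs).T @ Bc / (n_sub - 1)
        rng_over_seq = corr.max(axis=0) - corr.min(axis=0)      # feat x behav
        best_behav = np.argmax(rng_over_seq, axis=1)
        score = rng_over_seq[np.arange(n_feat), best_behav]
        hi = np.argmax(corr[:, np.arange(n_feat), best_behav], axis=0)
        lo = np.argmin(corr[:, np.arange(n_feat), best_behav], axis=0)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    score = np.where(eligible, score, -np.inf)
    order = np.argsort(-score, kind="stable")
    n_avail = int(eligible.sum())
    if k > n_avail:
        import warnings

        warnings.warn(f"only {n_avail} eligible measures for k={k}; retaining all", stacklevel=2)
        k = n_avail
    idx = np.sort(order[:k])
    sel = FeatureSelection(method=method, indices=idx, skew_excluded=excluded, fitted_on=fitted_on)
    if method == "dynamic":
        sel.dynamic_hi_lo = np.column_stack([hi[idx], lo[idx]])
    return sel


@dataclass
class PLSResult:
    x_saliences: np.ndarray        # p x n_comp
    y_saliences: np.ndarray        # q x n_comp
    score_correlations: np.ndarray
    singular_values: np.ndarray
    perm_p: np.ndarray | None = None
    n_perm: int = 0


def _standardize(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, float)
    sd = M.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant column(s) {bad.tolist()} in {name}")
    return (M - M.mean(axis=0)) / sd


class PLSPermutation(BaseEstimator):
    """Symmetric PLS-SVD with row-permutation inference.

    ``fit(X, Y)`` standardizes both matrices, takes the SVD of the
    cross-covariance, records sign-aligned score correlations per component
    and (if ``n_perm > 0``) their permutation p-values.  Attributes follow
    scikit-learn convention (``x_saliences_``, ``perm_p_``, ...).
    """

    def __init__(self, n_components: int = 10, n_perm: int = 5000, seed: int = 0, mode: str = "svd"):
        self.n_components = n_components
        self.n_perm = n_perm
        self.seed = seed
        self.mode = mode

    def _svd_stats(self, Xs, Ys, n_comp):
        if self.mode == "regression":
            return self._regression_stats(Xs, Ys, n_comp)
        if self.mode != "svd":
            raise ValueError(f"unknown PLS mode {self.mode!r}")
        C = Xs.T @ Ys / (Xs.shape[0] - 1)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        U, s, V = U[:, :n_comp], s[:n_comp], Vt[:n_comp].T
        tx = Xs @ U
        ty = Ys @ V
        r = np.empty(s.size)
        for k in range(s.size):
            r[k] = np.corrcoef(tx[:, k], ty[:, k])[0, 1]
        flip = np.sign(r)
        flip[flip == 0] = 1.0
        return U, V * flip, np.abs(r), s

    @staticmethod
    def _regression_stats(Xs, Ys, n_comp):
        """Regression-mode variant via NIPALS (scikit-learn PLSRegression)."""
        from sklearn.cross_decomposition import PLSRegression

        est = PLSRegression(n_components=n_comp, scale=False).fit(Xs, Ys)
        tx, ty = est.x_scores_, est.y_scores_
        r = np.array([np.corrcoef(tx[:, k], ty[:, k])[0, 1] for k in range(n_comp)])
        flip = np.sign(r)
        flip[flip == 0] = 1.0
        sv = np.linalg.norm(tx, axis=0) * np.linalg.norm(ty, axis=0)
        return est.x_weights_, est.y_weights_ * flip, np.abs(r), sv

    def fit(self, X, Y):
        Xs = _standardize(X, "X")
        Ys = _standardize(Y, "Y")
        n = Xs.shape[0]
        if n <= self.n_components:
            raise ValueError("need more samples than components")
        n_comp = min(self.n_components, min(Xs.shape[1], Ys.shape[1]))
        U, V, r, s = self._svd_stats(Xs, Ys, n_comp)
        self.x_saliences_, self.y_saliences_ = U, V
        self.score_correlations_, self.singular_values_ = r, s
        if self.n_perm:
            if self.n_perm < 100:
                import warnings

                warnings.warn(f"n_perm={self.n_perm} is very low", stacklevel=2)
            rng = np.random.default_rng(self.seed)
            exceed = np.zeros(n_comp)
            for _ in range(self.n_perm):
                Yp = Ys[rng.permutation(n)]
                _, _, rp, _ = self._svd_stats(Xs, Yp, n_comp)
                exceed += rp >= r
            self.perm_p_ = (1.0 + exceed) / (self.n_perm + 1.0)
        else:
            self.perm_p_ = None
        return self

    def result(self) -> PLSResult:
        return PLSResult(
            x_saliences=self.x_saliences_,
            y_saliences=self.y_saliences_,
            score_correlations=self.score_correlations_,
            singular_values=self.singular_values_,
            perm_p=self.perm_p_,
            n_perm=self.n_perm if self.perm_p_ is not None else 0,
        )


def pls_fit(X: np.ndarray, Y: np.ndarray, n_comp: int = 10) -> PLSResult:
    """PLS-SVD without permutation inference."""
    return PLSPermutation(n_components=n_comp, n_perm=0).fit(X, Y).result()


def pls_permutation(X: np.ndarray, Y: np.ndarray, n_perm: int = 5000, seed: int = 0, n_comp: int = 10) -> PLSResult:
    """PLS-SVD with row-permutation p-values (Y rows permuted, X intact)."""
    return PLSPermutation(n_components=n_comp, n_perm=n_perm, seed=seed).fit(X, Y).result()


@dataclass
class CorrespondenceReport:
    x_diagonal: np.ndarray
    y_diagonal: np.ndarray
    x_offset: np.ndarray           # train k vs test k+1
    y_offset: np.ndarray
    sign_flips: np.ndarray
    explained_variance_train: np.ndarray
    explained_variance_test: np.ndarray


def _aligned_corr(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    r = float(np.corrcoef(a, b)[0, 1])
    return (abs(r), -1 if r < 0 else 1)


def correspondence(train: PLSResult, test: PLSResult) -> CorrespondenceReport:
    """Sign-aligned train/test salience correlations, diagonal and offset-1."""
    if train.x_saliences.shape[0] != test.x_saliences.shape[0]:
        raise ValueError("train and test use different feature inventories")
    k = min(train.x_saliences.shape[1], test.x_saliences.shape[1])
    xd, yd, flips = [], [], []
    for c in range(k):
        rx, fx = _aligned_corr(train.x_saliences[:, c], test.x_saliences[:, c])
        # the same flip applies to X and Y saliences of a component
        ry = float(np.corrcoef(train.y_saliences[:, c], fx * test.y_saliences[:, c])[0, 1])
        xd.append(rx)
        yd.append(ry)
        flips.append(fx)
    xo = [
        _aligned_corr(train.x_saliences[:, c], test.x_saliences[:, c + 1])[0] for c in range(k - 1)
    ]
    yo = [
        _aligned_corr(train.y_saliences[:, c], test.y_saliences[:, c + 1])[0] for c in range(k - 1)
    ]
    ev = lambda res: res.singular_values**2 / np.sum(res.singular_values**2)  # noqa: E731
    return CorrespondenceReport(
        x_diagonal=np.array(xd),
        y_diagonal=np.array(yd),
        x_offset=np.array(xo),
        y_offset=np.array(yo),
        sign_flips=np.array(flips),
        explained_variance_train=ev(train),
        explained_variance_test=ev(test),
    )


def pca_correspondence(X_train: np.ndarray, X_test: np.ndarray, n_comp: int = 10) -> dict:
    """PCA loading correlations across cohorts (diagonal and offset-1)."""
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("cohorts must share columns")

    def loadings(M):
        Z = _standardize(M, "X")
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        return Vt[: min(n_comp, Vt.shape[0])].T

    Lt, Le = loadings(X_train), loadings(X_test)
    k = min(Lt.shape[1], Le.shape[1])
    diag = np.array([_aligned_corr(Lt[:, c], Le[:, c])[0] for c in range(k)])
    off = np.array([_aligned_corr(Lt[:, c], Le[:, c + 1])[0] for c in range(k - 1)])
    return {"diagonal": diag, "offset": off}


def replication_thresholds(n_training_significant: int, alpha: float = 0.05) -> float | None:
    """Testing-sample corrected alpha: alpha / training-significant count."""
    if n_training_significant < 0:
        raise ValueError("count must be nonnegative")
    if n_training_significant == 0:
        return None
    return bonferroni(alpha, n_training_significant)
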