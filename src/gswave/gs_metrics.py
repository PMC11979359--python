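"""Global-signal (GS) summary metrics across wavelet scales.

Three metrics per subject x sequence x scale:

* ``mean_correlation`` -- mean of the Fisher-z wavelet correlations over all
  region pairs (averaged on the z scale);
* ``median_regional_variance`` -- median across regions of the per-scale
  wavelet variance (log-transformed before aggregation across subjects);
* ``gs_timeseries_variance`` -- per-scale wavelet variance of the global
  (region-mean) series (log-transformed); in ``raw`` mode this is computed
  from the pre-nuisance global series.

Modes: ``raw`` (no GS removal), ``standard_gsr`` (the unweighted global
series is regressed out of every region first), ``weighted_gsr`` (regions
are z-scored before forming the global series, equalizing regional
contributions, then that series is regressed out).  Sequence-averaged
metrics are z-scored across subjects into the subject x 18 analysis matrix
(3 metrics x 6 scales).

Order analyses use the centered unit-spacing linear contrast
(+/-2.5, +/-1.5, +/-0.5); group analyses regress each of the 18 measures on
a predictor plus five motion principal components with the study's
sequential Bonferroni scheme (alpha/54 in training; alpha/(training hits) in
testing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import bonferroni
from .wavelet import modwt_decompose, wavelet_variance

__all__ = [
    "GSMetricTable",
    "gs_timeseries",
    "sequence_gs_metrics",
    "compute_gs_table",
    "tsnr",
    "linear_order_contrast",
    "order_contrast_weights",
    "gs_group_regression",
]

N_SCALES = 6
METRICS = ("mean_correlation", "median_regional_variance", "gs_timeseries_variance")
LOG_METRICS = ("median_regional_variance", "gs_timeseries_variance")


def gs_timeseries(data: np.ndarray, weighted: bool = False) -> np.ndarray:
    """Global series of a time x region matrix.

    Unweighted: plain region mean.  Weighted: mean of per-region z-scored
    series, so low-amplitude regions contribute equally; zero-variance
    regions are dropped with a warning.
    """
    X = np.asarray(data, float)
    if not weighted:
        return X.mean(axis=1)
    sd = X.std(axis=0, ddof=1)
    good = sd > 0
    if not good.all():
        import warnings

        warnings.warn(f"dropping {int((~good).sum())} zero-variance regions from weighted GS", stacklevel=2)
    Z = (X[:, good] - X[:, good].mean(axis=0)) / sd[good]
    return Z.mean(axis=1)


def remove_gs(data: np.ndarray, gs: np.ndarray) -> np.ndarray:
    """Regress the global series (plus intercept) out of every region."""
    X = np.column_stack([np.ones_like(gs), gs])
    beta, *_ = np.linalg.lstsq(X, np.asarray(data, float), rcond=None)
    return data - X @ beta


def sequence_gs_metrics(
    data: np.ndarray,
    raw_data: np.ndarray | None = None,
    mode: str = "raw",
    levels: int = N_SCALES,
) -> dict[str, np.ndarray]:
    """Per-scale GS metrics of one cleaned sequence matrix.

    ``raw_data`` supplies the pre-nuisance matrix used for the raw-mode GS
    variance ("after normalization but prior to nuisance correction").
    """
    X = np.asarray(data, float)
    if mode == "standard_gsr":
        X = remove_gs(X, gs_timeseries(X, weighted=False))
    elif mode == "weighted_gsr":
        X = remove_gs(X, gs_timeseries(X, weighted=True))
    elif mode != "raw":
        raise ValueError(f"unknown mode {mode!r}")
    dec = modwt_decompose(X.T, levels=levels)
    mean_corr = np.empty(levels)
    med_var = np.empty(levels)
    for j in range(1, levels + 1):
        W = dec.details[j - 1]  # regions x time coefficients
        C = np.corrcoef(W)
        iu = np.triu_indices_from(C, k=1)
        r = np.clip(C[iu], -1 + 1e-12, 1 - 1e-12)
        mean_corr[j - 1] = np.mean(np.arctanh(r))
        med_var[j - 1] = np.median(wavelet_variance(dec, j))
    gs_source = np.asarray(raw_data, float) if (mode == "raw" and raw_data is not None) else X
    g = gs_timeseries(gs_source, weighted=(mode == "weighted_gsr"))
    gdec = modwt_decompose(g, levels=levels)
    gs_var = np.array([wavelet_variance(gdec, j) for j in range(1, levels + 1)])
    return {
        "mean_correlation": mean_corr,
        "median_regional_variance": med_var,
        "gs_timeseries_variance": gs_var,
    }


@dataclass
class GSMetricTable:
    """Aggregated subject x 18 GS measure matrix plus per-sequence values."""

    aggregated: pd.DataFrame           # subject x 18 (z-scored)
    per_sequence: pd.DataFrame         # tidy: subject, sequence, scale, metric, value
    mode: str

    @property
    def measure_names(self) -> list[str]:
        return list(self.aggregated.columns)


def _agg_columns() -> list[str]:
    return [f"{m}_scale{j}" for m in METRICS for j in range(1, N_SCALES + 1)]


def signed_log(x: np.ndarray) -> np.ndarray:
    """sign(x) * log(1 + |x|): a log-like transform defined for negatives."""
    x = np.asarray(x, float)
    return np.sign(x) * np.log1p(np.abs(x))


def compute_gs_table(
    cohort_data: dict, mode: str = "raw", levels: int = N_SCALES, strict_paper_log: bool = False
) -> GSMetricTable:
    """GS metric table for a cohort.

    ``cohort_data`` maps subject id -> list of per-sequence dicts with keys
    ``data`` (cleaned time x region matrix), optional ``raw`` (pre-nuisance
    matrix), ``order`` (1-based acquisition position).  Subjects missing any
    sequence are flagged and excluded from the aggregate.
    """
    tidy_rows = []
    agg_rows = {}
    n_seq = max(len(v) for v in cohort_data.values())
    for sid, seqs in cohort_data.items():
        if len(seqs) < n_seq:
            import warnings

            warnings.warn(f"subject {sid} missing sequences; excluded from aggregate", stacklevel=2)
            continue
        per_metric = {m: np.empty((n_seq, levels)) for m in METRICS}
        for q, seq in enumerate(seqs):
            vals = sequence_gs_metrics(seq["data"], seq.get("raw"), mode=mode, levels=levels)
            for m in METRICS:
                per_metric[m][q] = vals[m]
                for j in range(levels):
                    tidy_rows.append(
                        {
                            "subject_id": sid,
                            "sequence": seq.get("order", q + 1),
                            "scale": j + 1,
                            "metric": m,
                            "value": vals[m][j],
                        }
                    )
        row = {}
        for m in METRICS:
            seq_mean = per_metric[m].mean(axis=0)
            if m in LOG_METRICS:
                seq_mean = np.log(seq_mean)
            elif strict_paper_log:
                # blanket-log variant: mean correlation can be negative, so
                # the signed log stands in for a plain log
                seq_mean = signed_log(seq_mean)
            for j in range(levels):
                row[f"{m}_scale{j + 1}"] = seq_mean[j]
        agg_rows[sid] = row
    agg = pd.DataFrame.from_dict(agg_rows, orient="index")[_agg_columns()]
    agg = (agg - agg.mean()) / agg.std(ddof=1)
    agg.index.name = "subject_id"
    return GSMetricTable(aggregated=agg, per_sequence=pd.DataFrame(tidy_rows), mode=mode)


def tsnr(raw_global_series: np.ndarray) -> float:
    """Temporal signal-to-noise ratio: mean / SD of the raw global series."""
    g = np.asarray(raw_global_series, float)
    sd = g.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-SD global series: tSNR undefined")
    return float(g.mean() / sd)


def order_contrast_weights(n: int = 6, sign_convention: str = "increase_positive") -> np.ndarray:
    """Centered unit-spacing linear contrast weights (|first| = 2.5 for n=6)."""
    w = np.arange(n, dtype=float) - (n - 1) / 2.0
    if sign_convention == "increase_positive":
        return w
    if sign_convention == "first_positive":
        return -w
    raise ValueError(f"unknown sign_convention {sign_convention!r}")


def linear_order_contrast(
    values: np.ndarray, sign_convention: str = "increase_positive"
) -> float:
    """Linear order contrast of per-sequence values (no missing values)."""
    v = np.asarray(values, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("missing per-sequence values in order contrast")
    return float(v @ order_contrast_weights(v.size, sign_convention))


def gs_group_regression(
    table: GSMetricTable | pd.DataFrame,
    predictor: np.ndarray,
    motion_pcs: np.ndarray,
    alpha: float = 0.05,
    n_demographics: int = 3,
) -> pd.DataFrame:
    """Per-measure regression of GS measures on a predictor + motion covariates.

    Returns slope, t, p per measure plus the training Bonferroni threshold
    ``alpha / (n_measures * n_demographics)`` and the significance decision.
    Collinear covariate columns are dropped with a warning.
    """
    agg = table.aggregated if isinstance(table, GSMetricTable) else table
    y_all = agg.values
    x = np.asarray(predictor, float)
    M = np.asarray(motion_pcs, float)
    if M.ndim == 1:
        M = M[:, None]
    design = np.column_stack([np.ones_like(x), x, M])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        import warnings

        keep = [0, 1]
        for c in range(2, design.shape[1]):
            if np.linalg.matrix_rank(design[:, keep + [c]]) > len(keep):
                keep.append(c)
        warnings.warn(
            f"dropping {design.shape[1] - len(keep)} collinear covariate column(s)", stacklevel=2
        )
        design = design[:, keep]
    n, p = design.shape
    pinv = np.linalg.pinv(design)
    beta = pinv @ y_all
    resid = y_all - design @ beta
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof
    xx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xx_inv[1, 1])
    tvals = beta[1] / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    threshold = bonferroni(alpha, len(agg.columns) * n_demographics)
    out = pd.DataFrame(
        {
            "measure": agg.columns,
            "slope": beta[1],
            "t": tvals,
            "p": pvals,
            "df": dof,
            "corrected_alpha": threshold,
            "significant": pvals < threshold,
        }
    )
    return out


def testing_threshold(n_training_hits: int, alpha: float = 0.05) -> float:
    """Testing-sample threshold: alpha / number of training-sample hits."""
    if n_training_hits < 1:
        raise ValueError("no training hits: nothing to test")
    return bonferroni(alpha, n_training_hits)
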