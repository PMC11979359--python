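"""Between-sequence reliability: ICC(3,1) for FC and variance measures.

ICC(3,1) (two-way mixed model, consistency, single measurement) treats the
six sequences as fixed "raters" of each subject-level measure:

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS)

with BMS/EMS the between-subject and residual mean squares of the two-way
(subject x sequence) layout.  Zero between-subject variance yields a defined
nonpositive value rather than an error.  The inventory covers every FC edge
at scales 3-5 and every regional variance measure, with regional mean-ICC
maps and cross-cohort profile correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["icc31", "icc21", "icc31_many", "ICCTable", "icc_inventory", "icc_summary"]

FC_SCALES = (3, 4, 5)


def icc31_many(Y: np.ndarray) -> np.ndarray:
    """Vectorized ICC(3,1) over the leading axes of ``Y`` (..., n, k)."""
    Y = np.asarray(Y, float)
    n, k = Y.shape[-2:]
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 sequences")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells are not allowed; exclude the measure instead")
    grand = Y.mean(axis=(-2, -1), keepdims=True)
    rows = Y.mean(axis=-1, keepdims=True)
    cols = Y.mean(axis=-2, keepdims=True)
    ss_rows = k * np.sum((rows - grand) ** 2, axis=(-2, -1))
    ss_err = np.sum((Y - rows - cols + grand) ** 2, axis=(-2, -1))
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (bms - ems) / denom, 0.0)
    return icc


def icc31(matrix: np.ndarray) -> float:
    """ICC(3,1) of one subject x sequence matrix."""
    return float(icc31_many(np.asarray(matrix, float)))


def icc21(matrix: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    Unlike the consistency form, systematic sequence (rater) offsets lower
    this coefficient.
    """
    Y = np.asarray(matrix, float)
    n, k = Y.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 sequences")
    grand = Y.mean()
    ss_rows = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_err = np.sum((Y - grand) ** 2) - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems + k * (jms - ems) / n
    return float((bms - ems) / denom) if denom > 0 else 0.0


@dataclass
class ICCTable:
    table: pd.DataFrame     # columns: measure, class, scale, icc (+ region ids)

    def summaries(self, measure_class: str | None = None) -> dict:
        t = self.table if measure_class is None else self.table[self.table["class"] == measure_class]
        v = t["icc"].values
        return icc_summary(v)


def icc_summary(iccs: np.ndarray) -> dict:
    v = np.asarray(iccs, float)
    return {
        "mean": float(v.mean()),
        "max": float(v.max()),
        "min": float(v.min()),
        "skewness": float(stats.skew(v, bias=False)),
        "fraction_above_0.6": float(np.mean(v > 0.6)),
        "n": int(v.size),
    }


def fc_edge_measures(fc_z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten (subjects, sequences, scales, R, R) FC arrays into edge measures.

    Returns (values with shape (n_edges*n_scales, subjects, sequences),
    region-pair index array, scale index array).
    """
    n_sub, n_seq, n_sc, R, _ = fc_z.shape
    iu = np.triu_indices(R, k=1)
    vals = fc_z[:, :, :, iu[0], iu[1]]              # sub x seq x scale x edge
    vals = np.moveaxis(vals, (2, 3), (0, 1))        # scale x edge x sub x seq
    flat = vals.reshape(n_sc * iu[0].size, n_sub, n_seq)
    pairs = np.tile(np.stack(iu, axis=1), (n_sc, 1))
    scales = np.repeat(np.arange(n_sc), iu[0].size)
    return flat, pairs, scales


def icc_inventory(
    fc_z: np.ndarray | None = None,
    variances: np.ndarray | None = None,
    fc_scales: tuple[int, ...] = FC_SCALES,
) -> ICCTable:
    """ICC per measure for FC (scales 3-5) and log regional variance.

    ``fc_z``: (subjects, sequences, scales, R, R) Fisher-z FC matrices;
    ``variances``: (subjects, sequences, scales, R) wavelet variances
    (logged here).  Regional mean-ICC maps are z-scored by the caller.
    """
    rows = []
    if fc_z is not None:
        flat, pairs, scale_idx = fc_edge_measures(np.asarray(fc_z, float))
        iccs = icc31_many(flat)
        for m, icc in enumerate(iccs):
            rows.append(
                {
                    "measure": f"fc_s{fc_scales[scale_idx[m]]}_{pairs[m, 0]}_{pairs[m, 1]}",
                    "class": "fc",
                    "scale": int(fc_scales[scale_idx[m]]),
                    "region_i": int(pairs[m, 0]),
                    "region_j": int(pairs[m, 1]),
                    "icc": float(icc),
                }
            )
    if variances is not None:
        V = np.log(np.asarray(variances, float))
        n_sub, n_seq, n_sc, R = V.shape
        flat = np.moveaxis(V, (2, 3), (0, 1)).reshape(n_sc * R, n_sub, n_seq)
        iccs = icc31_many(flat)
        for m, icc in enumerate(iccs):
            sc, r = divmod(m, R)
            rows.append(
                {
                    "measure": f"var_s{fc_scales[sc] if sc < len(fc_scales) else sc + 1}_{r}",
                    "class": "variance",
                    "scale": int(fc_scales[sc]) if sc < len(fc_scales) else sc + 1,
                    "region_i": int(r),
                    "region_j": -1,
                    "icc": float(icc),
                }
            )
    return ICCTable(table=pd.DataFrame(rows))


def regional_mean_icc(table: ICCTable, measure_class: str, n_regions: int) -> np.ndarray:
    """Per-region mean ICC (FC: mean over all edges touching the region)."""
    t = table.table[table.table["class"] == measure_class]
    sums = np.zeros(n_regions)
    counts = np.zeros(n_regions)
    for _, row in t.iterrows():
        sums[row["region_i"]] += row["icc"]
        counts[row["region_i"]] += 1
        if row["region_j"] >= 0:
            sums[row["region_j"]] += row["icc"]
            counts[row["region_j"]] += 1
    counts[counts == 0] = 1
    mean = sums / counts
    return (mean - mean.mean()) / mean.std(ddof=1)
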