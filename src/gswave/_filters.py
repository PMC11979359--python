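"""Shared GLM-style discrete-cosine high-pass projection."""

from __future__ import annotations

import numpy as np

__all__ = ["dct_highpass"]


def dct_highpass(x: np.ndarray, tr: float, cutoff_seconds: float = 128.0) -> np.ndarray:
    """Project out discrete-cosine components slower than ``cutoff_seconds``.

    The classic fMRI GLM high-pass: a basis of the constant plus the
    ``K = floor(2 * T * tr / cutoff)`` slowest cosines is regressed out.
    Well-conditioned at any series length (unlike very-low-cutoff recursive
    filters, whose impulse responses can exceed the series).
    """
    X = np.asarray(x, float)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    T = X.shape[0]
    K = int(np.floor(2.0 * T * tr / cutoff_seconds))
    t = np.arange(T)
    basis = [np.ones(T)]
    for k in range(1, K + 1):
        basis.append(np.cos(np.pi * k * (2 * t + 1) / (2 * T)))
    B = np.column_stack(basis)
    beta, *_ = np.linalg.lstsq(B, X, rcond=None)
    out = X - B @ beta
    return out[:, 0] if one_d else out
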