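"""Maximal overlap discrete wavelet transform (MODWT) machinery.

The MODWT is an undecimated, shift-covariant wavelet transform that splits a
time series into approximately octave frequency bands ("scales").  For a
series sampled every ``tr`` seconds, scale ``j`` covers roughly
``[f_N / 2**j, f_N / 2**(j-1)]`` with Nyquist ``f_N = 1/(2*tr)``; at
TR = 1.5 s scale 1 is 0.17-0.33 Hz and scale 6 is ~0.005-0.01 Hz.

The default analysis wavelet is the 8-tap Daubechies least-asymmetric filter
("la8", ``sym4`` in PyWavelets' naming), the standard choice for BOLD
functional-connectivity work.  Boundary handling is by reflection: the series
is mirror-extended to length 2N, a circular MODWT is run, and the first N
coefficients are kept.  Per-scale variance and correlation estimators use the
non-boundary coefficients (count ``N - L_j + 1`` with
``L_j = (2**j - 1)(L - 1) + 1``) when enough exist, falling back to all N
coefficients (flagged as biased) otherwise -- short fMRI sequences do not
support unbiased estimation at the deepest scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletDecomposition",
    "ScaleBand",
    "modwt_decompose",
    "scale_frequency_band",
    "wavelet_variance",
    "wavelet_variances",
    "wavelet_correlation",
]

#: minimal non-boundary coefficient count before falling back to the biased
#: (all-coefficient) estimator
_MIN_UNBIASED = 8


def _la8_filters(wavelet: str = "la8") -> tuple[np.ndarray, np.ndarray]:
    """Return the MODWT scaling and wavelet filters (g~, h~) = (g, h)/sqrt(2).

    The wavelet filter follows the quadrature-mirror relation
    ``h_l = (-1)**l * g_{L-1-l}``.
    """
    name = "sym4" if wavelet == "la8" else wavelet
    g = np.asarray(pywt.Wavelet(name).rec_lo, dtype=float)
    L = g.size
    h = ((-1.0) ** np.arange(L)) * g[::-1]
    return g / np.sqrt(2.0), h / np.sqrt(2.0)


def filter_length(wavelet: str = "la8") -> int:
    return _la8_filters(wavelet)[0].size * 2  # g~ already /sqrt(2); length only


def equivalent_filter_width(scale: int, L: int = 8) -> int:
    """L_j = (2**j - 1)(L - 1) + 1, the scale-j equivalent filter width."""
    return (2**scale - 1) * (L - 1) + 1


def _filt(V: np.ndarray, taps: np.ndarray, step: int) -> np.ndarray:
    """Circularly filter along the last axis with an upsampled-by-step filter."""
    N = V.shape[-1]
    idx = (np.arange(N)[None, :] - step * np.arange(taps.size)[:, None]) % N
    return np.einsum("l,...ln->...n", taps, V[..., idx])


def _ifilt(W: np.ndarray, taps: np.ndarray, step: int) -> np.ndarray:
    N = W.shape[-1]
    idx = (np.arange(N)[None, :] + step * np.arange(taps.size)[:, None]) % N
    return np.einsum("l,...ln->...n", taps, W[..., idx])


def modwt_synthesis(
    details_ext: np.ndarray, smooth_ext: np.ndarray, wavelet: str = "la8"
) -> np.ndarray:
    """Inverse MODWT from (possibly re-weighted) circular coefficients.

    Linearity makes this the cheap route to band-limited components:
    synthesizing ``gain_j * W_j`` equals ``sum_j gain_j * D_j``.
    """
    g, h = _la8_filters(wavelet)
    J = details_ext.shape[0]
    V = smooth_ext
    for k in range(J, 0, -1):
        V = _ifilt(details_ext[k - 1], h, 2 ** (k - 1)) + _ifilt(V, g, 2 ** (k - 1))
    return V


@dataclass
class ScaleBand:
    """Approximate frequency band [f_low, f_high] (Hz) covered by a scale."""

    scale: int
    f_low: float
    f_high: float


def scale_frequency_band(scale: int, tr_seconds: float) -> ScaleBand:
    """Nominal MODWT band for ``scale`` at sampling interval ``tr_seconds``.

    band = [f_N / 2**scale, f_N / 2**(scale-1)] with f_N = 1/(2*tr).
    """
    if not 1 <= int(scale):
        raise ValueError(f"scale must be >= 1, got {scale}")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    f_nyq = 1.0 / (2.0 * tr_seconds)
    return ScaleBand(int(scale), f_nyq / 2**scale, f_nyq / 2 ** (scale - 1))


@dataclass
class WaveletDecomposition:
    """MODWT of one or more series (last axis = time).

    ``details[j-1]`` holds the scale-j wavelet coefficients on the original
    support (length N); ``smooth`` the level-``levels`` scaling coefficients.
    The full reflected-circular coefficients are kept privately so that the
    additive multiresolution analysis (MRA) reconstructs the input exactly.
    """

    details: np.ndarray          # (levels, ..., N)
    smooth: np.ndarray           # (..., N)
    wavelet_name: str
    boundary: str
    n: int
    _details_ext: np.ndarray = field(repr=False, default=None)
    _smooth_ext: np.ndarray = field(repr=False, default=None)

    @property
    def levels(self) -> int:
        return self.details.shape[0]

    def n_nonboundary(self, scale: int) -> int:
        """N_hat_j = max(N - L_j + 1, 0) non-boundary coefficients at scale j."""
        return max(self.n - equivalent_filter_width(scale) + 1, 0)

    def mra(self) -> tuple[np.ndarray, np.ndarray]:
        """Additive components (D_1..D_J, S_J); their sum equals the input."""
        g, h = _la8_filters(self.wavelet_name)
        J = self.levels
        comps = []
        for j in range(1, J + 1):
            V = np.zeros_like(self._smooth_ext)
            for k in range(J, 0, -1):
                W = self._details_ext[k - 1] if k == j else np.zeros_like(V)
                V = _ifilt(W, h, 2 ** (k - 1)) + _ifilt(V, g, 2 ** (k - 1))
            comps.append(V[..., : self.n])
        V = self._smooth_ext
        for k in range(J, 0, -1):
            V = _ifilt(np.zeros_like(V), h, 2 ** (k - 1)) + _ifilt(V, g, 2 ** (k - 1))
        return np.stack(comps), V[..., : self.n]

    def reconstruct(self) -> np.ndarray:
        D, S = self.mra()
        return D.sum(axis=0) + S


def modwt_decompose(
    series: np.ndarray,
    levels: int = 6,
    wavelet: str = "la8",
    boundary: str = "reflection",
) -> WaveletDecomposition:
    """Decompose ``series`` (time on the last axis) into ``levels`` scales.

    Raises ``ValueError`` for series shorter than ``2**levels``.
    """
    x = np.asarray(series, dtype=float)
    N = x.shape[-1]
    if N < 2**levels:
        raise ValueError(
            f"series of length {N} is too short for a level-{levels} MODWT "
            f"(need at least {2 ** levels} points)"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if boundary == "reflection":
        xe = np.concatenate([x, x[..., ::-1]], axis=-1)
    elif boundary == "circular":
        xe = x
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    g, h = _la8_filters(wavelet)
    V = xe
    dets = []
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        dets.append(_filt(V, h, step))
        V = _filt(V, g, step)
    details_ext = np.stack(dets)
    return WaveletDecomposition(
        details=details_ext[..., :N],
        smooth=V[..., :N],
        wavelet_name=wavelet,
        boundary=boundary,
        n=N,
        _details_ext=details_ext,
        _smooth_ext=V,
    )


def _coeff_subset(dec: WaveletDecomposition, scale: int) -> tuple[np.ndarray, int, bool]:
    """Coefficients used for estimation at ``scale`` plus (count, biased flag)."""
    W = dec.details[scale - 1]
    m = dec.n_nonboundary(scale)
    if m >= _MIN_UNBIASED:
        return W[..., equivalent_filter_width(scale) - 1 :], m, False
    if dec.n < 2:
        raise ValueError("not enough coefficients for variance estimation")
    return W, dec.n, True


def wavelet_variance(
    series: np.ndarray | WaveletDecomposition,
    scale: int,
    levels: int = 6,
    wavelet: str = "la8",
    return_flag: bool = False,
):
    """MODWT wavelet variance of ``series`` at ``scale``.

    Unbiased (non-boundary coefficients) when possible, biased over all N
    coefficients otherwise.  ``return_flag`` additionally returns whether the
    biased fallback was used.
    """
    dec = (
        series
        if isinstance(series, WaveletDecomposition)
        else modwt_decompose(series, levels=max(levels, scale), wavelet=wavelet)
    )
    W, m, biased = _coeff_subset(dec, scale)
    var = np.mean(W**2, axis=-1)
    return (var, biased) if return_flag else var


def wavelet_variances(
    series: np.ndarray, levels: int = 6, wavelet: str = "la8"
) -> np.ndarray:
    """Per-scale wavelet variances, shape ``(levels, ...)``."""
    dec = modwt_decompose(series, levels=levels, wavelet=wavelet)
    return np.stack([wavelet_variance(dec, j) for j in range(1, levels + 1)])


_bartlett_cache: dict[tuple[str, int], float] = {}


def bartlett_factor(scale: int, wavelet: str = "la8", grid: int = 8192) -> float:
    """Variance-inflation factor of scale-j coefficient correlations.

    MODWT detail coefficients are serially correlated; for white-noise input
    the variance of a sample correlation over M coefficients is C_j / M with
    ``C_j = sum_k rho_j(k)**2`` (Bartlett), where rho_j is the level-j
    equivalent filter autocorrelation.  C_j ~ 0.63 * 2**j for la8.
    """
    key = (wavelet, int(scale))
    if key not in _bartlett_cache:
        g, h = _la8_filters(wavelet)
        N = grid

        def circ(taps, step):
            full = np.zeros(N)
            full[: taps.size * step : step] = taps
            return np.fft.fft(full)

        Gprod = np.ones(N, dtype=complex)
        for j in range(1, int(scale) + 1):
            Hj = circ(h, 2 ** (j - 1)) * Gprod
            if j == int(scale):
                acov = np.real(np.fft.ifft(np.abs(Hj) ** 2))
                _bartlett_cache[key] = float(np.sum((acov / acov[0]) ** 2))
            Gprod = Gprod * circ(g, 2 ** (j - 1))
    return _bartlett_cache[key]


def wavelet_correlation(
    x: np.ndarray,
    y: np.ndarray,
    scale: int,
    levels: int = 6,
    wavelet: str = "la8",
    df_convention: str = "effective",
) -> tuple[float, float, int]:
    """Per-scale wavelet correlation between two equal-length series.

    Returns ``(r, z, df)`` where r is the Pearson correlation of the scale-j
    detail coefficients and ``z = atanh(r) * sqrt(df - 3)`` is the Fisher
    variance-stabilized statistic.  ``df`` conventions: ``"effective"``
    (default) divides the non-boundary count N_hat_j by the Bartlett factor
    C_j so the null z is standard normal despite coefficient autocorrelation;
    ``"nonboundary"`` uses N_hat_j itself; ``"conservative"`` uses
    N_hat_j / 2**j.  When too few non-boundary coefficients exist all N are
    used (biased fallback).  |r| = 1 yields a signed-infinite z.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    dx = modwt_decompose(x, levels=max(levels, scale), wavelet=wavelet)
    dy = modwt_decompose(y, levels=max(levels, scale), wavelet=wavelet)
    Wx, m, biased = _coeff_subset(dx, scale)
    Wy, _, _ = _coeff_subset(dy, scale)
    if np.std(Wx) == 0 or np.std(Wy) == 0:
        raise ValueError("zero-variance wavelet coefficients: correlation undefined")
    r = float(np.corrcoef(Wx, Wy)[0, 1])
    if df_convention == "effective":
        df = max(int(round(m / bartlett_factor(scale, wavelet))), 4)
    elif df_convention == "conservative":
        df = max(int(m / 2**scale), 4)
    elif df_convention == "nonboundary":
        df = m
    else:
        raise ValueError(f"unknown df_convention {df_convention!r}")
    if abs(r) >= 1.0 - 1e-15:
        z = np.inf * np.sign(r)
    else:
        z = float(np.arctanh(r) * np.sqrt(max(df - 3, 1)))
    return r, z, df


def band_component(
    series: np.ndarray, scales: tuple[int, ...], levels: int = 6, wavelet: str = "la8"
) -> np.ndarray:
    """Sum of the MRA components for ``scales`` (smooth included iff levels in scales...).

    Convenience band filter used for low-frequency-restricted analyses:
    the returned series contains only the requested scales' content.
    """
    dec = modwt_decompose(series, levels=levels, wavelet=wavelet)
    gain = np.zeros(levels)
    for j in scales:
        gain[j - 1] = 1.0
    smooth_gain = 1.0 if levels in scales else 0.0
    out = modwt_synthesis(
        gain[(...,) + (None,) * dec._smooth_ext.ndim] * dec._details_ext,
        smooth_gain * dec._smooth_ext,
        wavelet,
    )
    return out[..., : dec.n]
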