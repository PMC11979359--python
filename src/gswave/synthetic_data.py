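"""Seeded synthetic cohorts with the statistical structure the analyses assume.

The generator emulates a two-cohort, six-sequence fMRI study design: each
subject contributes six regional BOLD matrices (default lengths
330/330/240/240/504/180 at TR = 1.5 s over a 278-region parcellation, 1824
time points in all), a framewise-displacement (FWD) motion trace per
sequence, and one row of a behavior/demographics table (26 questionnaire
scales + age + sex-like binary group + education = 29 analysis columns).

Signal model (per subject x sequence): a low-rank spatial process ---

    X[t, r] = w_r * G_t + sum_k B[r, k] * L_k[t] + artifact + noise_sd * eps

where ``G`` is a global mode with positive regional weights ``w`` (the
global-signal topography), ``L_k`` are local spatial modes, and ``eps`` is
white idiosyncratic noise.  Temporal sources are built by MODWT
multiresolution filtering of white noise, which gives direct control of each
source's per-scale (frequency-band) variance.  Planted effects:

* group 1's low-frequency source components (scales 4-6 + smooth) are
  multiplied by ``group_lowfreq_scale``;
* regional variance drifts linearly with acquisition order
  (``order_variance_slope`` per position);
* the global-mode loading drifts with order (``order_meancorr_slope``),
  moving the mean inter-regional correlation;
* group 1's FWD trace has a larger high-frequency/low-frequency variance
  ratio (``hf_motion_ratio_effect`` on the log ratio);
* behavior scales follow a latent factor model shared between cohorts.

All latent components (global mode, structured signal, artifact, noise,
spike frames) are stored so downstream estimators can be checked against
ground truth.  All randomness flows from ``CohortSpec.seed`` through
``numpy.random.default_rng`` stream spawning; identical specs give
bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .wavelet import modwt_decompose, modwt_synthesis

__all__ = [
    "CohortSpec",
    "RegionalTimeSeriesSet",
    "MotionTrace",
    "Subject",
    "Cohort",
    "generate_cohort",
    "generate_regional_bold",
    "generate_fwd_series",
    "generate_behavior",
    "simulate_fbm",
    "lowfreq_scale_for_cohens_d",
]

_DEFAULT_LENGTHS = (330, 330, 240, 240, 504, 180)
_N_SCALES = 6
_LOWFREQ_SCALES = (4, 5, 6)


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of one synthetic cohort.

    ``group_lowfreq_scale`` multiplies the low-frequency (scales 4-6 + smooth)
    signal amplitude in group 1 relative to group 0.  With subjects' overall
    signal amplitude lognormal with log-sd ``subject_amp_sd``, a scale factor
    ``exp(d * subject_amp_sd)`` plants a population Cohen's d of ``d`` on log
    low-frequency variance (see :func:`lowfreq_scale_for_cohens_d`).
    """

    n_per_group: int = 55
    sequence_lengths: tuple[int, ...] = _DEFAULT_LENGTHS
    tr_seconds: float = 1.5
    n_regions: int = 278
    group_lowfreq_scale: float = 1.0
    order_variance_slope: float = 0.0
    order_meancorr_slope: float = 0.0
    hf_motion_ratio_effect: float = 0.0
    n_latent_factors: int = 4
    behavior_loadings: np.ndarray | None = None
    noise_sd: float = 1.0
    seed: int = 0
    # secondary knobs (documented defaults; not study parameters)
    n_local_modes: int = 10
    subject_amp_sd: float = 0.25
    gs_strength: float = 1.0
    artifact_strength: float = 0.0
    n_noise_pool: int = 60
    spike_rate: float = 0.0
    fwd_gamma_shape: float = 2.0
    fwd_gamma_scale: float = 0.1
    n_behavior_scales: int = 26
    behavior_noise_sd: float = 0.6
    motion_heterogeneity: float = 1.0

    def __post_init__(self):
        if any(n < 64 for n in self.sequence_lengths):
            raise ValueError("all sequence lengths must be >= 64")
        if self.n_regions < 4:
            raise ValueError("n_regions must be >= 4")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.group_lowfreq_scale <= 0:
            raise ValueError("group_lowfreq_scale must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_lengths)

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_per_group

    @property
    def total_timepoints(self) -> int:
        return int(sum(self.sequence_lengths))


def lowfreq_scale_for_cohens_d(d: float, subject_amp_sd: float = 0.25) -> float:
    """Low-frequency scale factor planting Cohen's d on log low-freq variance.

    Log scale-j variance of the signal is ``const + 2*ln(a_i) + 2*ln(s)`` for
    group 1 with subject amplitude a_i ~ lognormal(0, sigma_a); the group mean
    difference is 2 ln s against a between-subject sd of 2 sigma_a, so
    ``d = ln(s)/sigma_a`` and ``s = exp(d * sigma_a)``.
    """
    return float(math.exp(d * subject_amp_sd))


@dataclass
class RegionalTimeSeriesSet:
    """One subject x sequence regional matrix (rows = time, cols = parcels)."""

    values: np.ndarray
    sequence_order: int            # 1-based acquisition position
    tr_seconds: float
    region_labels: list[str]

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regional time series contain non-finite values")


@dataclass
class MotionTrace:
    """FWD series (length T-1, mm, nonnegative) + six rigid-body series."""

    fwd: np.ndarray
    params: np.ndarray             # (T, 6): 3 translations mm, 3 rotations rad

    def __post_init__(self):
        if np.any(self.fwd < 0):
            raise ValueError("FWD must be nonnegative")


@dataclass
class Latents:
    """Ground-truth components stored for oracle-based tests."""

    gs: np.ndarray                 # global mode series (time,)
    gs_weights: np.ndarray         # regional weights of the global mode
    signal: np.ndarray             # structured (global+local) part, time x region
    lowfreq_signal: np.ndarray     # scales 4-6 + smooth part of the signal
    artifact: np.ndarray           # artifact series added to data and noise pool
    noise: np.ndarray              # idiosyncratic white part, time x region
    spike_frames: np.ndarray       # indices of injected motion spikes
    amp: float                     # subject amplitude multiplier


@dataclass
class Subject:
    subject_id: str
    group: int
    sequences: list[RegionalTimeSeriesSet]
    motion: list[MotionTrace]
    noise_pool: list[np.ndarray]   # per sequence: time x n_noise_pool series
    latents: list[Latents]


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject]
    behavior: pd.DataFrame

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def _banded_sources(
    rng: np.random.Generator, n: int, n_src: int, band_gain: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """White-noise sources re-weighted per MODWT band.

    Returns ``(full, lowfreq)`` of shape ``(n_src, n)``:
    ``full = sum_j gain_j * D_j + gain_s * S`` and ``lowfreq`` the same sum
    restricted to scales 4-6 + smooth (the low-frequency content).
    """
    w = rng.standard_normal((n_src, n))
    dec = modwt_decompose(w, levels=_N_SCALES)
    lf_gain = np.zeros_like(band_gain)
    for j in _LOWFREQ_SCALES:
        lf_gain[j - 1] = band_gain[j - 1]
    lf_gain[_N_SCALES] = band_gain[_N_SCALES]

    def _synth(gv):
        out = modwt_synthesis(
            gv[:_N_SCALES, None, None] * dec._details_ext, gv[_N_SCALES] * dec._smooth_ext
        )
        return out[..., :n]

    return _synth(band_gain), _synth(lf_gain)


def _banded_source(rng: np.random.Generator, n: int, band_gain: np.ndarray) -> np.ndarray:
    return _banded_sources(rng, n, 1, band_gain)[0][0]


def _source_gains() -> np.ndarray:
    """1/f-shaped band gains shared by structured sources and noise.

    Using the same temporal band profile for signal and noise keeps the
    per-band signal-to-noise ratio constant, so the group low-frequency
    amplitude scaling (applied to signal and noise alike) leaves the
    inter-regional correlation structure untouched -- it is a pure scaling
    phenomenon that per-region z-scoring removes.
    """
    return np.array(
        [2.0 ** (0.5 * (j - 1)) for j in range(1, _N_SCALES + 1)] + [2.0 ** (0.5 * _N_SCALES)]
    )


def _gain_norm(g: np.ndarray) -> float:
    """Approximate sd of a banded source with gains ``g`` (white input)."""
    band_var = np.array([2.0 ** -j for j in range(1, _N_SCALES + 1)] + [2.0 ** -_N_SCALES])
    return float(np.sqrt(np.sum(g**2 * band_var)))


def generate_regional_bold(spec: CohortSpec) -> Cohort:
    """Full cohort (BOLD + motion + noise pool + behavior); see module docs."""
    return generate_cohort(spec)


def generate_cohort(spec: CohortSpec) -> Cohort:
    rng = np.random.default_rng(spec.seed)
    ss = rng.spawn(3)
    bold_rng, motion_rng, behav_rng = ss
    labels = [f"R{r:03d}" for r in range(spec.n_regions)]
    # cohort-level spatial structure, shared across subjects
    struct_rng = np.random.default_rng(spec.seed + 2**20)
    gs_w = np.abs(struct_rng.normal(1.0, 0.35, size=spec.n_regions))
    B = struct_rng.normal(0.0, 0.6, size=(spec.n_regions, spec.n_local_modes))
    art_w = np.abs(struct_rng.normal(0.8, 0.2, size=spec.n_regions))

    subjects: list[Subject] = []
    groups = np.repeat([0, 1], spec.n_per_group)
    for i, grp in enumerate(groups):
        srng = bold_rng.spawn(1)[0]
        mrng = motion_rng.spawn(1)[0]
        amp = float(np.exp(srng.normal(0.0, spec.subject_amp_sd)))
        motion_profile = _subject_motion_profile(mrng, spec, grp)
        lf = spec.group_lowfreq_scale if grp == 1 else 1.0
        gains = _source_gains()
        noise_gains = gains / _gain_norm(gains)
        seqs, motions, pools, lats = [], [], [], []
        for q, n_t in enumerate(spec.sequence_lengths):
            order = q + 1
            var_mult = 1.0 + spec.order_variance_slope * (order - 1)
            if var_mult <= 0:
                raise ValueError("order_variance_slope drives variance nonpositive")
            gs_mult = spec.gs_strength * (1.0 + spec.order_meancorr_slope * (order - 1))
            # temporal sources: one global + local modes, built in one batch
            src, src_lf = _banded_sources(srng, n_t, 1 + spec.n_local_modes, gains)
            scale = amp * math.sqrt(var_mult)
            gs0 = scale * src[0]
            local = scale * src[1:].T                      # time x n_local_modes
            structured = gs_mult * np.outer(gs0, gs_w) + 0.35 * (local @ B.T)
            gs0_lf = scale * src_lf[0]
            local_lf = scale * src_lf[1:].T
            structured_lf = gs_mult * np.outer(gs0_lf, gs_w) + 0.35 * (local_lf @ B.T)
            nz, nz_lf = _banded_sources(srng, n_t, spec.n_regions, noise_gains)
            nsd = spec.noise_sd * math.sqrt(var_mult)
            noise = nsd * nz.T
            noise_lf = nsd * nz_lf.T
            # group low-frequency amplitude scaling applies to the complete
            # series (signal and noise alike): X <- X + (s - 1) * lowband(X)
            signal = structured + (lf - 1.0) * structured_lf
            noise_scaled = noise + (lf - 1.0) * noise_lf
            gs = gs0 + (lf - 1.0) * gs0_lf
            lowfreq = lf * structured_lf
            artifact = spec.artifact_strength * _banded_source(srng, n_t, gains)
            data = signal + np.outer(artifact, art_w) + noise_scaled
            # noise pool: artifact + white, plus occasional component spikes
            pool = 0.8 * np.outer(artifact, np.ones(spec.n_noise_pool)) + srng.standard_normal(
                (n_t, spec.n_noise_pool)
            ) * (1.0 + srng.uniform(0, 1.5, size=spec.n_noise_pool))
            fwd, params, spike_frames = _fwd_trace(mrng, n_t, spec, motion_profile)
            seqs.append(
                RegionalTimeSeriesSet(
                    values=data, sequence_order=order, tr_seconds=spec.tr_seconds, region_labels=labels
                )
            )
            motions.append(MotionTrace(fwd=fwd, params=params))
            pools.append(pool)
            lats.append(
                Latents(
                    gs=gs,
                    gs_weights=gs_w,
                    signal=signal,
                    lowfreq_signal=lowfreq,
                    artifact=artifact,
                    noise=noise_scaled,
                    spike_frames=spike_frames,
                    amp=amp,
                )
            )
        subjects.append(
            Subject(
                subject_id=f"S{i:04d}",
                group=int(grp),
                sequences=seqs,
                motion=motions,
                noise_pool=pools,
                latents=lats,
            )
        )
    behavior = generate_behavior(spec, rng=behav_rng, groups=groups)
    return Cohort(spec=spec, subjects=subjects, behavior=behavior)


def _subject_motion_profile(rng: np.random.Generator, spec: CohortSpec, group: int) -> dict:
    """Per-subject motion idiosyncrasies, persistent across sequences.

    Between-subject heterogeneity in overall magnitude (gamma scale), shape,
    and high-frequency share gives the metric covariance a dominant general
    "mover" factor plus a frequency-content factor, the structure the cohort
    PCA is meant to summarize.
    """
    beta0 = 0.45
    beta = beta0 * math.exp(0.5 * spec.hf_motion_ratio_effect) if group == 1 else beta0
    het = spec.motion_heterogeneity
    return {
        "scale_mult": float(np.exp(rng.normal(0.0, 0.4 * het))),
        "shape_mult": float(np.exp(rng.normal(0.0, 0.2 * het))),
        "beta": float(np.clip(beta * np.exp(rng.normal(0.0, 0.25 * het)), 0.05, 0.95)),
        "phi": float(np.clip(0.95 + 0.03 * het * rng.standard_normal(), 0.8, 0.995)),
    }


def _fwd_trace(
    rng: np.random.Generator, n_t: int, spec: CohortSpec, profile: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gamma-marginal FWD with AR(1) temporal structure + Bernoulli spikes.

    A latent Gaussian mixes a slow AR(1) process with white noise; group 1
    receives a larger white-noise share so that its high (scales 1-2) to low
    (scale 6) frequency wavelet-variance ratio is raised by
    ``hf_motion_ratio_effect`` on the log scale (in expectation).  The
    Gaussian copula maps the latent process onto a gamma marginal.
    """
    m = n_t - 1
    phi = profile["phi"]
    slow = np.empty(m)
    slow[0] = rng.standard_normal() / math.sqrt(1 - phi**2)
    eps = rng.standard_normal(m - 1)
    for t in range(1, m):
        slow[t] = phi * slow[t - 1] + eps[t - 1]
    slow *= math.sqrt(1 - phi**2)  # unit variance
    fast = rng.standard_normal(m)
    beta = profile["beta"]
    u = math.sqrt(1 - beta**2) * slow + beta * fast
    fwd = stats.gamma.ppf(
        np.clip(stats.norm.cdf(u), 1e-12, 1 - 1e-12),
        a=spec.fwd_gamma_shape * profile["shape_mult"],
        scale=spec.fwd_gamma_scale * profile["scale_mult"],
    )
    spike_frames = np.flatnonzero(rng.random(m) < spec.spike_rate)
    fwd[spike_frames] += rng.uniform(1.0, 2.0, size=spike_frames.size)
    # rigid-body parameters: smooth AR series, translations mm / rotations rad
    params = np.empty((n_t, 6))
    for c in range(6):
        p = np.empty(n_t)
        p[0] = 0.0
        pe = rng.standard_normal(n_t - 1)
        for t in range(1, n_t):
            p[t] = 0.98 * p[t - 1] + 0.02 * pe[t - 1]
        params[:, c] = p * (1.0 if c < 3 else 0.01)
    return fwd, params, spike_frames


def _default_loadings(rng: np.random.Generator, n_scales: int, n_factors: int) -> np.ndarray:
    """Block-ish loading matrix: each scale loads mainly on one factor."""
    lam = 0.15 * rng.standard_normal((n_scales, n_factors))
    for s in range(n_scales):
        lam[s, s % n_factors] += 0.8
    return lam


def generate_behavior(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Behavior/demographics table: 26 z-scored scale columns + age/sex/education.

    Scales = loadings @ latent factors + noise; the loading matrix is fixed by
    the spec (not the seed) so independently seeded "train" and "test"
    cohorts share the factor structure in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 7)
    if groups is None:
        groups = np.repeat([0, 1], spec.n_per_group)
    n = len(groups)
    lam = spec.behavior_loadings
    if lam is None:
        lam = _default_loadings(np.random.default_rng(12345), spec.n_behavior_scales, spec.n_latent_factors)
    lam = np.asarray(lam, float)
    if lam.shape[0] != spec.n_behavior_scales:
        raise ValueError("behavior_loadings rows must equal n_behavior_scales")
    if np.linalg.matrix_rank(lam) < min(lam.shape):
        import warnings

        warnings.warn("behavior loading matrix is rank deficient", stacklevel=2)
    F = rng.standard_normal((n, lam.shape[1]))
    scales = F @ lam.T + spec.behavior_noise_sd * rng.standard_normal((n, lam.shape[0]))
    sd = scales.std(axis=0, ddof=1)
    if np.all(sd > 0):
        scales = (scales - scales.mean(axis=0)) / sd
    cols = {f"scale_{i + 1:02d}": scales[:, i] for i in range(lam.shape[0])}
    cols["age"] = np.round(rng.uniform(18, 25, size=n), 1)
    cols["sex"] = groups.astype(int)
    cols["education"] = rng.integers(3, 8, size=n).astype(float)
    df = pd.DataFrame(cols, index=[f"S{i:04d}" for i in range(n)])
    df.index.name = "subject_id"
    return df


def generate_fwd_series(spec: CohortSpec) -> list[list[MotionTrace]]:
    """Motion traces only (per subject, per sequence)."""
    cohort = generate_cohort(spec)
    return [s.motion for s in cohort.subjects]


# --------------------------------------------------------------------------
# fractional Brownian motion (used to validate the Hurst estimators)

def simulate_fbm(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fBm path of length ``n`` via circulant embedding of fGn.

    Falls back to Cholesky factorization if the embedding is not nonnegative
    definite (rare for H in (0, 1)).
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must be in (0, 1)")
    m = n - 1

    def gamma_(k):
        k = np.abs(k).astype(float)
        return 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))

    row = gamma_(np.arange(m))
    circ = np.concatenate([row, row[-2:0:-1]])
    lam = np.fft.rfft(circ).real
    if np.min(lam) < -1e-8:
        cov = gamma_(np.subtract.outer(np.arange(m), np.arange(m)))
        Lch = np.linalg.cholesky(cov + 1e-12 * np.eye(m))
        fgn = Lch @ rng.standard_normal(m)
    else:
        lam = np.clip(lam, 0, None)
        M = circ.size
        z = rng.standard_normal(M) + 1j * rng.standard_normal(M)
        zf = np.fft.fft(z)
        spec_full = np.clip(np.fft.fft(circ).real, 0, None)
        fgn = np.real(np.fft.ifft(zf * np.sqrt(spec_full / M)))[:m] * math.sqrt(M)
    return np.concatenate([[0.0], np.cumsum(fgn)])


# --------------------------------------------------------------------------
# plain-text export (tidy matrices + confounds-style TSV + manifest)

def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write TSV matrices, confounds TSVs, behavior CSV and a YAML manifest."""
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tr_seconds": cohort.spec.tr_seconds,
        "sequence_lengths": list(cohort.spec.sequence_lengths),
        "subjects": [],
    }
    for s in cohort.subjects:
        entry = {"subject_id": s.subject_id, "group": s.group, "sequences": []}
        for seq, mot in zip(s.sequences, s.motion):
            stem = f"{s.subject_id}_seq{seq.sequence_order}"
            pd.DataFrame(seq.values, columns=seq.region_labels).to_csv(
                out / f"{stem}_bold.tsv", sep="\t", index=False
            )
            conf = pd.DataFrame(
                mot.params, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
            )
            conf["framewise_displacement"] = np.concatenate([[np.nan], mot.fwd])
            conf.to_csv(out / f"{stem}_confounds.tsv", sep="\t", index=False)
            entry["sequences"].append(
                {"order": seq.sequence_order, "bold": f"{stem}_bold.tsv", "confounds": f"{stem}_confounds.tsv"}
            )
        manifest["subjects"].append(entry)
    cohort.behavior.to_csv(out / "behavior.csv")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def train_test_specs(spec: CohortSpec, test_seed_offset: int = 10_007) -> tuple[CohortSpec, CohortSpec]:
    """A train/test pair of specs differing only in seed."""
    return spec, replace(spec, seed=spec.seed + test_seed_offset)
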