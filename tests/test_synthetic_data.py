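"""Generator contracts: determinism, study structure, planted-effect oracles."""

import numpy as np
import pytest
from scipy import stats

from gswave.synthetic_data import (
    CohortSpec,
    generate_behavior,
    generate_cohort,
    lowfreq_scale_for_cohens_d,
    simulate_fbm,
)
from gswave.wavelet import wavelet_variances


def tiny_spec(**kw):
    base = dict(n_per_group=4, sequence_lengths=(128,) * 2, n_regions=10, seed=5)
    base.update(kw)
    return CohortSpec(**base)


class TestStructure:
    def test_default_total_timepoints(self):
        """Six sequences of 330/330/240/240/504/180 give 1824 points."""
        assert CohortSpec().total_timepoints == 2 * 330 + 2 * 240 + 504 + 180 == 1824

    def test_shapes_and_labels(self, small_cohort):
        spec = small_cohort.spec
        for sub in small_cohort.subjects:
            assert len(sub.sequences) == spec.n_sequences
            for q, seq in enumerate(sub.sequences):
                assert seq.values.shape == (spec.sequence_lengths[q], spec.n_regions)
                assert seq.sequence_order == q + 1
                assert np.all(np.isfinite(seq.values))
            for mot, seq in zip(sub.motion, sub.sequences):
                assert mot.fwd.size == seq.values.shape[0] - 1
                assert np.all(mot.fwd >= 0)
                assert mot.params.shape == (seq.values.shape[0], 6)

    def test_behavior_has_29_columns(self, small_cohort):
        assert small_cohort.behavior.shape[1] == 29
        assert {"age", "sex", "education"} <= set(small_cohort.behavior.columns)

    @pytest.mark.parametrize(
        "kw", [dict(sequence_lengths=(32,)), dict(n_regions=2), dict(tr_seconds=0.0),
               dict(group_lowfreq_scale=-1.0)]
    )
    def test_invalid_spec_raises(self, kw):
        with pytest.raises(ValueError):
            tiny_spec(**kw)


class TestDeterminism:
    def test_bit_identical_under_same_seed(self):
        a = generate_cohort(tiny_spec())
        b = generate_cohort(tiny_spec())
        for sa, sb in zip(a.subjects, b.subjects):
            for qa, qb in zip(sa.sequences, sb.sequences):
                assert np.array_equal(qa.values, qb.values)
            for ma, mb in zip(sa.motion, sb.motion):
                assert np.array_equal(ma.fwd, mb.fwd)
        assert a.behavior.equals(b.behavior)

    def test_different_seeds_differ(self):
        a = generate_cohort(tiny_spec(seed=1))
        b = generate_cohort(tiny_spec(seed=2))
        assert not np.array_equal(a.subjects[0].sequences[0].values, b.subjects[0].sequences[0].values)


class TestPlantedLowFreqEffect:
    def test_latent_lowfreq_component_scales_exactly(self):
        """Against the stored latent: the planted scale multiplies the
        low-frequency component exactly, so its variance ratio is s**2."""
        s = 1.5
        base = generate_cohort(tiny_spec(group_lowfreq_scale=1.0, subject_amp_sd=0.0))
        scaled = generate_cohort(tiny_spec(group_lowfreq_scale=s, subject_amp_sd=0.0))
        for sub_b, sub_s in zip(base.subjects, scaled.subjects):
            lb = sub_b.latents[0].lowfreq_signal
            ls = sub_s.latents[0].lowfreq_signal
            expected = s if sub_b.group == 1 else 1.0
            assert np.allclose(ls, expected * lb)
            assert np.var(ls) / np.var(lb) == pytest.approx(expected**2, rel=1e-10)

    def test_no_effect_when_scale_is_one(self):
        """group_lowfreq_scale=1 with no drifts: scale-5 variance ratio ~ 1."""
        spec = CohortSpec(
            n_per_group=12, sequence_lengths=(256,) * 2, n_regions=12, seed=3,
            group_lowfreq_scale=1.0, subject_amp_sd=0.0,
        )
        c = generate_cohort(spec)
        g = c.groups()
        mv = np.array(
            [np.mean([np.median(wavelet_variances(q.values.T, 6)[4]) for q in s.sequences])
             for s in c.subjects]
        )
        ratio = np.median(mv[g == 1]) / np.median(mv[g == 0])
        assert 0.7 < ratio < 1.4

    def test_measured_scale5_ratio_tracks_plant(self):
        spec = CohortSpec(
            n_per_group=10, sequence_lengths=(256,) * 2, n_regions=12, seed=3,
            group_lowfreq_scale=1.5, subject_amp_sd=0.0,
        )
        c = generate_cohort(spec)
        g = c.groups()
        mv = np.array(
            [np.mean([np.median(wavelet_variances(q.values.T, 6)[4]) for q in s.sequences])
             for s in c.subjects]
        )
        ratio = np.median(mv[g == 1]) / np.median(mv[g == 0])
        assert ratio == pytest.approx(2.25, rel=0.30)  # sampling noise at this n

    def test_monotone_in_parameter(self):
        """The matched estimator moves monotonically with the planted scale."""
        ratios = []
        for s in (1.0, 1.3, 1.6):
            med = {0: [], 1: []}
            for rep in range(4):
                spec = CohortSpec(
                    n_per_group=6, sequence_lengths=(192,), n_regions=10,
                    seed=100 + rep, group_lowfreq_scale=s, subject_amp_sd=0.0,
                )
                c = generate_cohort(spec)
                for sub in c.subjects:
                    med[sub.group].append(np.median(wavelet_variances(sub.sequences[0].values.T, 6)[4]))
            ratios.append(np.median(med[1]) / np.median(med[0]))
        assert ratios[0] < ratios[1] < ratios[2]


class TestOrderEffects:
    def test_variance_drift_across_order(self):
        spec = CohortSpec(
            n_per_group=8, sequence_lengths=(128,) * 6, n_regions=10, seed=9,
            order_variance_slope=0.15, subject_amp_sd=0.0,
        )
        c = generate_cohort(spec)
        per_order = np.zeros(6)
        for sub in c.subjects:
            for q, lat in enumerate(sub.latents):
                per_order[q] += lat.signal.var()
        assert np.all(np.diff(per_order) > 0) or stats.spearmanr(np.arange(6), per_order).statistic > 0.9


class TestMotionTraces:
    def test_gamma_marginal_recovery(self):
        """MLE on a long trace recovers the configured gamma shape within 10%."""
        spec = CohortSpec(n_per_group=1, sequence_lengths=(1801,), n_regions=4, seed=21,
                          motion_heterogeneity=0.0)
        c = generate_cohort(spec)
        fwd = c.subjects[0].motion[0].fwd
        shape, _, scale = stats.gamma.fit(fwd, floc=0)
        assert shape == pytest.approx(2.0, rel=0.10)
        assert scale == pytest.approx(0.1, rel=0.15)

    def test_no_spikes_when_rate_zero(self):
        c = generate_cohort(tiny_spec(spike_rate=0.0, motion_heterogeneity=0.0))
        for sub in c.subjects:
            for mot in sub.motion:
                assert mot.fwd.max() < 1.0

    def test_spikes_recorded_in_latents(self):
        c = generate_cohort(tiny_spec(spike_rate=0.05, seed=2))
        any_spikes = False
        for sub in c.subjects:
            for mot, lat in zip(sub.motion, sub.latents):
                if lat.spike_frames.size:
                    any_spikes = True
                    assert np.all(mot.fwd[lat.spike_frames] > 1.0)
        assert any_spikes

    def test_null_hf_ratio_calibration(self):
        """hf_motion_ratio_effect=0: group test non-significant in >=90% of
        replicates at alpha=0.05 (200 seeded replicates)."""
        from gswave.wavelet import wavelet_variances as wv

        nonsig = 0
        n_rep = 200
        for rep in range(n_rep):
            spec = CohortSpec(
                n_per_group=6, sequence_lengths=(128,), n_regions=4,
                seed=1000 + rep, hf_motion_ratio_effect=0.0,
            )
            c = generate_cohort(spec)
            g = c.groups()
            ratios = []
            for sub in c.subjects:
                v = wv(sub.motion[0].fwd, levels=6)
                ratios.append(np.log(v[:2].sum() / v[5]))
            ratios = np.array(ratios)
            p = stats.ttest_ind(ratios[g == 1], ratios[g == 0]).pvalue
            nonsig += p >= 0.05
        assert nonsig / n_rep >= 0.90

    def test_hf_ratio_effect_recovered(self):
        spec = CohortSpec(
            n_per_group=20, sequence_lengths=(256,) * 2, n_regions=4, seed=4,
            hf_motion_ratio_effect=1.0,
        )
        c = generate_cohort(spec)
        g = c.groups()
        ratios = []
        for sub in c.subjects:
            v = np.mean([wavelet_variances(m.fwd, 6) for m in sub.motion], axis=0)
            ratios.append(np.log(v[:2].sum() / v[5]))
        ratios = np.array(ratios)
        t = stats.ttest_ind(ratios[g == 1], ratios[g == 0])
        assert t.statistic > 0 and t.pvalue < 0.05


class TestBehavior:
    def test_single_factor_no_noise_perfect_correlation(self):
        spec = tiny_spec(n_latent_factors=1, behavior_noise_sd=0.0,
                         behavior_loadings=np.ones((26, 1)))
        df = generate_behavior(spec)
        scales = df[[c for c in df.columns if c.startswith("scale_")]].values
        C = np.corrcoef(scales.T)
        assert np.min(np.abs(C)) > 1 - 1e-10

    def test_two_factor_population_correlation(self):
        """Empirical correlations match loadings @ loadings.T + noise diag."""
        lam = np.zeros((26, 2))
        lam[:13, 0] = 0.9
        lam[13:, 1] = 0.9
        spec = CohortSpec(n_per_group=2500, sequence_lengths=(64,), n_regions=4,
                          behavior_loadings=lam, behavior_noise_sd=0.5, seed=8)
        df = generate_behavior(spec)
        scales = df[[c for c in df.columns if c.startswith("scale_")]].values
        emp = np.corrcoef(scales.T)
        pop_cov = lam @ lam.T + 0.25 * np.eye(26)
        d = np.sqrt(np.diag(pop_cov))
        pop = pop_cov / np.outer(d, d)
        assert np.max(np.abs(emp - pop)) < 0.05

    def test_rank_deficient_loadings_warn(self):
        lam = np.ones((26, 3))
        with pytest.warns(UserWarning, match="rank deficient"):
            generate_behavior(tiny_spec(behavior_loadings=lam))


class TestFBM:
    def test_increment_variance_and_self_similarity(self, rng):
        x = simulate_fbm(4096, 0.7, rng)
        inc = np.diff(x)
        assert inc.var() == pytest.approx(1.0, rel=0.15)
        # var(B(2k)-B(0)) / var(B(k)-B(0)) = 2**(2H)
        lag = 64
        v1 = np.var(x[lag:] - x[:-lag])
        v2 = np.var(x[2 * lag:] - x[:-2 * lag])
        assert np.log2(v2 / v1) == pytest.approx(2 * 0.7, abs=0.35)

    def test_invalid_hurst_raises(self, rng):
        with pytest.raises(ValueError):
            simulate_fbm(128, 1.5, rng)
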