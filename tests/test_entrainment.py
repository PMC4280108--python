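import numpy as np
import pytest
from scipy import stats

import hemisync as hs
from hemisync.core import EventStream
from hemisync.entrainment import ENTROPY_BAND_GROUPS
from hemisync.spectral import FREQS, SpectralEstimate


class TestRaoSpacing:
    def test_identical_angles_analytic_u(self):
        # n=10 coincident angles: nine zero spacings and one 360 deg arc
        u, _ = hs.rao_spacing_test(np.full(10, 1.234), n_mc=200, seed=0)
        assert u == pytest.approx(324.0)

    def test_equispaced_angles_zero_u(self):
        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        u, p = hs.rao_spacing_test(angles, n_mc=200, seed=0)
        assert u == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_von_mises_concentration_detected(self, seed):
        rng = np.random.default_rng(seed)
        angles = rng.vonmises(0.0, 2.0, size=100)
        _, p = hs.rao_spacing_test(angles, n_mc=5000, seed=seed)
        assert p < 0.001

    def test_p_uniform_under_null(self):
        # p-values of uniform samples must themselves be uniform
        rng = np.random.default_rng(7)
        ps = [
            hs.rao_spacing_test(rng.uniform(-np.pi, np.pi, 20), n_mc=1000, seed=k)[1]
            for k in range(200)
        ]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            hs.rao_spacing_test(np.array([0.1, 0.2, 0.3]))


class TestKuiper:
    def test_same_sample_not_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 2 * np.pi, 50)
        v, p = hs.kuiper_two_sample(a, a)
        assert v < 0.05 and p > 0.9

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.vonmises(0.0, 1.0, 60)
        b = rng.vonmises(1.0, 1.0, 60)
        v1, p1 = hs.kuiper_two_sample(a, b)
        v2, p2 = hs.kuiper_two_sample(a + 1.7, b + 1.7)
        assert v1 == pytest.approx(v2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_opposed_von_mises_detected(self):
        rng = np.random.default_rng(2)
        a = rng.vonmises(0.0, 2.0, 200)
        b = rng.vonmises(np.pi, 2.0, 200)
        _, p = hs.kuiper_two_sample(a, b)
        assert p < 0.001

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValueError):
            hs.kuiper_two_sample(np.zeros(5), np.zeros(20))


class TestBinomialCriterion:
    @pytest.mark.parametrize("k,expected", [(27, True), (26, False), (28, True), (0, False)])
    def test_study_rule(self, k, expected):
        assert hs.binomial_group_criterion(k) is expected

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            hs.binomial_group_criterion(29, total=28)


def _trigger_stream(times):
    return EventStream([(float(t), "tacs_trigger") for t in times])


class TestPhasesAtTriggers:
    def test_sine_at_rising_zero_crossings_is_phase_locked(self, layout):
        rate, dur = 1000.0, 20.0
        t = np.arange(int(rate * dur)) / rate
        data = np.tile(np.sin(2 * np.pi * 40.0 * t), (31, 1))
        rec = hs.Recording(data=data, rate=rate, layout=layout)
        trig = _trigger_stream(np.arange(0.75, dur - 1.0, 0.75))
        ps = hs.phases_at_triggers(rec, trig, {"gamma": ("gamma1",)})
        ang = ps.angles["gamma"][0]
        # circular SD of a concentrated sample
        r = np.abs(np.exp(1j * ang).mean())
        assert np.sqrt(-2 * np.log(r)) < 0.1

    def test_quarter_period_shift_rotates_mean_phase(self, layout):
        rate, dur = 1000.0, 20.0
        t = np.arange(int(rate * dur)) / rate
        data = np.tile(np.sin(2 * np.pi * 40.0 * t), (31, 1))
        rec = hs.Recording(data=data, rate=rate, layout=layout)
        base = np.arange(0.75, dur - 1.0, 0.75)
        ps0 = hs.phases_at_triggers(rec, _trigger_stream(base), {"g": ("gamma1",)})
        ps1 = hs.phases_at_triggers(
            rec, _trigger_stream(base + 1 / 160.0), {"g": ("gamma1",)}
        )
        m0 = np.angle(np.exp(1j * ps0.angles["g"][0]).mean())
        m1 = np.angle(np.exp(1j * ps1.angles["g"][0]).mean())
        delta = np.angle(np.exp(1j * (m1 - m0)))
        assert delta == pytest.approx(np.pi / 2, abs=0.1)

    def test_white_noise_phases_uniform(self, layout):
        rng = np.random.default_rng(3)
        rate, dur = 500.0, 60.0
        data = rng.standard_normal((31, int(rate * dur)))
        rec = hs.Recording(data=data, rate=rate, layout=layout)
        trig = _trigger_stream(np.arange(0.75, dur - 1.0, 0.75))
        ps = hs.phases_at_triggers(rec, trig, {"alpha": ("alpha",)})
        _, p = hs.rao_spacing_test(ps.angles["alpha"][0], n_mc=2000, seed=0)
        assert p > 0.05  # no spurious locking

    def test_out_of_range_triggers_skipped(self, layout):
        rec = hs.Recording(
            data=np.zeros((31, 1000)) + np.random.default_rng(0).standard_normal((31, 1000)),
            rate=1000.0,
            layout=layout,
        )
        trig = _trigger_stream([0.1, 0.5, 5.0])
        ps = hs.phases_at_triggers(rec, trig, {"alpha": ("alpha",)})
        assert ps.n_triggers == 2 and ps.n_skipped == 1

    def test_dummy_triggers_at_cadence(self, layout):
        rec = hs.Recording(data=np.zeros((31, 6000)), rate=1000.0, layout=layout)
        ev = EventStream([(0.5, "trial_start"), (6.0, "trial_end")])
        dummies = hs.make_dummy_triggers(rec, ev)
        times = dummies.times("dummy_trigger")
        assert times[0] == 0.5  # first trial sample
        assert np.allclose(np.diff(times), 0.75)


def _estimate_from_power(power):
    layout = hs.default_layout()
    pairs = layout.pairs
    cross = np.zeros((len(pairs), 100), dtype=complex)
    return SpectralEstimate(
        freqs=FREQS.copy(),
        power=power,
        cross=cross,
        pairs=tuple(pairs),
        n_segments=4,
        layout=layout,
    )


class TestSpectralEntropy:
    def test_uniform_power_maximal_entropy(self):
        em = hs.spectral_entropy(_estimate_from_power(np.ones((31, 100))))
        # equal share 1/31 at every frequency: H = width * log(31)/31 per band
        for name, members in ENTROPY_BAND_GROUPS.items():
            width = sum(
                hs.default_bands().bands[m][1] - hs.default_bands().bands[m][0] + 1
                for m in members
            )
            expected = width * np.log(31) / 31
            assert np.allclose(em.entropy[name], expected)

    def test_one_hot_power_zero_entropy(self):
        power = np.zeros((31, 100))
        power[4, 9] = 123.0  # all 10 Hz power in one channel
        em = hs.spectral_entropy(_estimate_from_power(power))
        assert em.entropy.loc[4, "alpha"] == pytest.approx(0.0, abs=1e-9)
        assert em.n_undefined == 99  # every other frequency row is empty

    def test_permutation_invariance_within_band(self):
        rng = np.random.default_rng(1)
        power = rng.random((31, 100)) + 0.1
        em1 = hs.spectral_entropy(_estimate_from_power(power))
        perm = power.copy()
        perm[:, 45:70] = perm[:, 45:70][:, ::-1]  # shuffle gamma2 freqs
        em2 = hs.spectral_entropy(_estimate_from_power(perm))
        assert np.allclose(em1.entropy["gamma"], em2.entropy["gamma"])

    def test_spectral_line_lowers_entropy(self):
        rng = np.random.default_rng(2)
        flat = rng.random((31, 100)) * 0.1 + 1.0
        lined = flat.copy()
        lined[20:26, 49] = 40.0  # strong 50 Hz line at a posterior subset
        em_flat = hs.spectral_entropy(_estimate_from_power(flat))
        em_line = hs.spectral_entropy(_estimate_from_power(lined))
        others = [c for c in range(31) if c not in range(20, 26)]
        # channels without the line lose their share: entropy drops there
        assert (
            em_line.entropy.loc[others, "gamma"].mean()
            < em_flat.entropy.loc[others, "gamma"].mean()
        )

    def test_per_channel_normalization_switch(self):
        rng = np.random.default_rng(3)
        power = rng.random((31, 100)) + 0.5
        em = hs.spectral_entropy(
            _estimate_from_power(power), normalization="across_frequencies"
        )
        assert em.normalization == "across_frequencies"
        assert np.isfinite(em.entropy.to_numpy()).all()
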