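"""Event detection, kinetics, percentage response, synchrony, JPSTH, bootstrap."""

import numpy as np
import pytest

from gliosim.events import (EventMatrix, bootstrap_sem, detect_ca_events,
                            event_kinetics, jpsth_cross_correlation,
                            percent_response, pinsky_rinzel_synchrony)

DT = 0.001


def _triangle(peak=1.0, base_width_s=0.2, dt=DT, pad=0.3):
    n_half = int(base_width_s / 2 / dt)
    up = np.linspace(0, peak, n_half + 1)
    tri = np.concatenate([up, up[-2::-1]])
    z = np.zeros(int(pad / dt))
    return np.concatenate([z, tri, z])


class TestDetection:
    def test_flat_subthreshold_trace_is_empty(self):
        assert detect_ca_events(np.full(1000, 0.1), DT) == []

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_ca_events(np.array([0.1, 0.2]), DT)

    def test_triangle_fwhm_is_half_base_width(self):
        recs = detect_ca_events(_triangle(peak=1.0, base_width_s=0.2), DT)
        assert len(recs) == 1
        assert recs[0].amplitude == pytest.approx(1.0)
        assert recs[0].fwhm == pytest.approx(0.1, abs=2 * DT)

    def test_overlapping_events_split_at_the_valley(self):
        a = _triangle(1.0, 0.2, pad=0.1)
        trace = np.concatenate([a, a])  # valley between the two peaks
        recs = detect_ca_events(trace, DT)
        assert len(recs) == 2

    def test_threshold_monotone(self, rng):
        trace = np.abs(np.cumsum(rng.normal(0, 0.05, 3000)))
        lo = detect_ca_events(trace, DT, threshold=0.3)
        hi = detect_ca_events(trace, DT, threshold=0.6)
        assert len(hi) <= len(lo)


class TestKinetics:
    def test_exponential_decay_time_equals_tau(self):
        tau = 0.05
        t = np.arange(0, 0.5, DT)
        trace = np.concatenate([np.zeros(50), 1.0 * np.exp(-t / tau)])
        _, decay = event_kinetics(trace, 50, DT)
        assert decay == pytest.approx(tau, abs=2 * DT)

    def test_linear_ramp_rise_is_60_percent_of_duration(self):
        T = 0.2
        ramp = np.linspace(0, 1, int(T / DT) + 1)
        trace = np.concatenate([np.zeros(20), ramp, ramp[-2::-1]])
        rise, _ = event_kinetics(trace, 20 + len(ramp) - 1, DT)
        assert rise == pytest.approx(0.6 * T, abs=2 * DT)

    def test_unresolved_limb_returns_none(self):
        # trace never falls below 20% on the left: rise undefined
        trace = np.concatenate([np.full(50, 0.9), np.linspace(0.9, 1.0, 50),
                                np.linspace(1.0, 0.0, 100)])
        rise, decay = event_kinetics(trace, 99, DT, left=0, right=198)
        assert rise is None
        assert decay is not None


class TestPercentResponse:
    def test_constant_trace_scores_unity(self):
        assert percent_response(np.full(4001, 0.5), DT, 2.0, 1.0) \
            == pytest.approx(1.0)

    def test_step_doubling_scores_two(self):
        trace = np.concatenate([np.ones(2000), 2 * np.ones(2001)])
        assert percent_response(trace, DT, 2.0, 2.0) == pytest.approx(
            2.0, rel=1e-3)

    def test_invariant_under_rescaling(self, rng):
        trace = 0.2 + np.abs(rng.normal(0, 0.1, 5001))
        r1 = percent_response(trace, DT, 2.5, 2.0)
        r2 = percent_response(7.3 * trace, DT, 2.5, 2.0)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_prestimulus_integral_signalled(self):
        trace = np.concatenate([np.zeros(1001), np.ones(1000)])
        with pytest.raises(ValueError, match="undefined"):
            percent_response(trace, DT, 1.0, 1.0)


def _brute_force_synchrony(trials, interval):
    """Independent straight-line reimplementation of the phase recipe:
    for every reference event, time differences to all other pooled
    events are wrapped by the probed inter-event interval and mapped to
    phases on the unit circle; the score is one minus the circular
    variance, averaged over reference events."""
    pooled = np.sort(np.concatenate([np.asarray(t) for t in trials]))
    scores = []
    for k, ref in enumerate(pooled):
        delta = np.delete(pooled, k) - ref
        phi = np.mod(delta, interval) / interval
        z = np.exp(2j * np.pi * phi)
        var = np.mean(np.abs(z - z.mean()) ** 2)
        scores.append(1 - var)
    return float(np.mean(scores))


class TestSynchrony:
    def test_identical_event_times_score_one(self):
        times = np.array([1.0, 3.0, 5.0, 7.0])
        m = EventMatrix([times.copy() for _ in range(8)])
        s = pinsky_rinzel_synchrony(m).synchrony[0]
        assert s == pytest.approx(1.0, abs=1e-9)

    def test_uniform_random_times_score_near_zero(self, rng):
        m = EventMatrix([np.sort(rng.uniform(0, 11, 40)) for _ in range(25)])
        s = pinsky_rinzel_synchrony(m).synchrony[0]
        assert s < 0.05

    def test_agrees_with_brute_force_reimplementation(self, rng):
        # two trials with a constant offset smaller than the event spacing
        base = np.arange(1.0, 6.0)
        trials = [base, base + 0.2]
        m = EventMatrix([t.copy() for t in trials])
        for iv in (1.0, 0.7):
            s = pinsky_rinzel_synchrony(m, intervals=[iv]).synchrony[0]
            assert s == pytest.approx(
                _brute_force_synchrony(trials, iv), abs=1e-12)

    def test_bounded_shift_and_permutation_invariant(self, rng):
        trials = [np.sort(rng.uniform(0, 8, 12)) for _ in range(6)]
        m = EventMatrix([t.copy() for t in trials])
        s = pinsky_rinzel_synchrony(m).synchrony[0]
        assert 0.0 <= s <= 1.0
        shifted = EventMatrix([t + 3.7 for t in trials])
        assert pinsky_rinzel_synchrony(shifted).synchrony[0] \
            == pytest.approx(s, abs=1e-12)
        perm = EventMatrix([trials[i].copy() for i in (4, 0, 5, 2, 1, 3)])
        assert pinsky_rinzel_synchrony(perm).synchrony[0] \
            == pytest.approx(s, abs=1e-12)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            pinsky_rinzel_synchrony(EventMatrix([np.array([1.0])]))


class TestCrossCorrelation:
    def test_identical_trains_score_one(self, rng):
        trials = [np.sort(rng.uniform(0, 11, rng.integers(3, 9)))
                  for _ in range(30)]
        m = EventMatrix([t.copy() for t in trials])
        peak, _ = jpsth_cross_correlation(m, EventMatrix(
            [t.copy() for t in trials]))
        assert peak == pytest.approx(1.0, abs=1e-9)

    def test_independent_trains_score_near_zero(self, rng):
        n, dens = 300, 60
        a = EventMatrix([np.sort(rng.uniform(0, 11, dens)) for _ in range(n)])
        b = EventMatrix([np.sort(rng.uniform(0, 11, dens)) for _ in range(n)])
        peak, prof = jpsth_cross_correlation(a, b)
        assert np.nanmean(prof) == pytest.approx(0.0, abs=0.05)
        assert peak < 0.35  # max over ~1100 null bins stays modest

    def test_degraded_copy_correlates_less(self, rng):
        trials = [np.sort(rng.uniform(0, 11, 8)) for _ in range(40)]
        ca = EventMatrix([t.copy() for t in trials])
        jittered = EventMatrix([np.sort(t + rng.normal(0, 0.5, t.size))
                                for t in trials])
        p_same, prof_same = jpsth_cross_correlation(
            ca, EventMatrix([t.copy() for t in trials]))
        p_jit, prof_jit = jpsth_cross_correlation(ca, jittered)
        assert np.nanmean(prof_same) > np.nanmean(prof_jit)

    def test_empty_event_set_rejected(self):
        full = EventMatrix([np.array([1.0, 2.0])] * 3)
        empty = EventMatrix([np.empty(0)] * 3)
        with pytest.raises(ValueError):
            jpsth_cross_correlation(full, empty)


class TestBootstrap:
    def test_constant_samples_zero_se(self, rng):
        assert bootstrap_sem(np.mean, np.full(100, 3.3), rng=rng) \
            == pytest.approx(0.0, abs=1e-12)

    def test_normal_mean_se_matches_clt(self, rng):
        x = rng.normal(0, 2.0, 1000)
        se = bootstrap_sem(np.mean, x, n_boot=200, sample_size=1000, rng=rng)
        assert se == pytest.approx(2.0 / np.sqrt(1000), rel=0.25)

    def test_degenerate_nboot_warns(self, rng):
        with pytest.warns(UserWarning):
            assert bootstrap_sem(np.mean, np.arange(5.0), n_boot=1,
                                 rng=rng) == 0.0

    def test_empty_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_sem(np.mean, [], rng=rng)
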