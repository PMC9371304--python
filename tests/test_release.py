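"""Dual-sensor release machinery: master equations, sampling, recycling."""

import numpy as np
import pytest
from scipy.linalg import expm

from gliosim.parameters import SensorParameters, VesiclePools
from gliosim.release import (characterize_clamped, initial_release_state,
                             pool_kinetics_step, release_rates,
                             sample_release_events, sensor_update,
                             syt7_rate_matrix)


class TestSensorUpdate:
    def test_syt4_half_occupancy_at_kd(self, sensors, pools):
        # at Ca2+ = kd the single-site sensor equilibrates at exactly 1/2
        st = initial_release_state(pools)
        ca = sensors.syt4_kd
        for _ in range(20000):  # 1 s, far past the ms-scale relaxation
            st = sensor_update(st, ca, sensors, 5e-5)
        assert st.syt4_bound == pytest.approx(0.5, abs=1e-3)

    def test_zero_calcium_drains_occupancy(self, sensors, pools):
        st = initial_release_state(pools)
        st.syt4_bound = 0.9
        st.syt7_occupancy = np.full(6, 1 / 6)
        for _ in range(40000):  # 2 s
            st = sensor_update(st, 0.0, sensors, 5e-5)
        assert st.syt4_bound < 1e-6
        assert st.syt7_occupancy[0] == pytest.approx(1.0, abs=1e-3)
        kr, ff = release_rates(st, sensors)
        assert ff == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("ca", [2.0, 15.0, 60.0])
    def test_matches_matrix_exponential_oracle(self, ca, sensors, pools):
        # clamped-Ca occupancy trajectory vs the closed-form linear-ODE
        # solution, max abs error < 1e-4
        # integrated at a refined step so discretization error does not
        # mask a master-equation defect
        st = initial_release_state(pools)
        Q = syt7_rate_matrix(ca, sensors)
        dt, n = 5e-6, 40000
        worst = 0.0
        w0 = st.syt7_occupancy.copy()
        for k in range(1, n + 1):
            st = sensor_update(st, ca, sensors, dt)
            if k % 8000 == 0:
                exact = expm(Q.T * (k * dt)) @ w0
                worst = max(worst, np.abs(st.syt7_occupancy - exact).max())
                s4_exact = (ca / (ca + sensors.syt4_kd)) * (
                    1 - np.exp(-(sensors.syt4_kon * ca + sensors.syt4_koff)
                               * k * dt))
                worst = max(worst, abs(st.syt4_bound - s4_exact))
        assert worst < 1e-4

    def test_oversized_dt_flagged(self, sensors, pools):
        st = initial_release_state(pools)
        with pytest.raises(ValueError):
            sensor_update(st, 1e4, sensors, 1e-2)


class TestReleaseSampling:
    def test_empty_docked_pool_never_releases(self, sensors, pools, rng):
        st = initial_release_state(pools)
        st.docked = 0
        st.syt4_bound = 1.0
        kr, ff = release_rates(st, sensors)
        assert kr == 0.0

    def test_zero_rates_leave_state_unchanged(self, sensors, pools, rng):
        st = initial_release_state(pools)
        out = sample_release_events(st, (0.0, 0.0), 5e-5, rng)
        assert out.docked == st.docked and out.mobile == st.mobile
        assert not out.event_times

    def test_bernoulli_thinning_expectation(self, pools, rng):
        # constant rate r over a window: mean release count ~ r*T
        r, dt, n, reps = 40.0, 5e-5, 4000, 60  # T = 0.2 s
        counts = []
        for _ in range(reps):
            st = initial_release_state(pools.replace(n_docked_init=10000,
                                                     docked_capacity=10000))
            c = 0
            for k in range(n):
                before = st.docked
                st = sample_release_events(st, (r, 0.0), dt, rng,
                                           time_s=k * dt)
                c += before - st.docked
            counts.append(c)
        expected = r * n * dt
        sem = np.std(counts) / np.sqrt(reps)
        assert abs(np.mean(counts) - expected) < 3 * sem + 1e-9

    def test_rate_dt_product_bounded(self, sensors, pools, rng):
        st = initial_release_state(pools)
        with pytest.raises(ValueError):
            sample_release_events(st, (1e6, 0.0), 5e-5, rng)


class TestPoolKinetics:
    def test_full_docked_pool_is_fixed_point(self, pools, rng):
        st = initial_release_state(pools.replace(n_mobile_init=0))
        for k in range(200):
            st = pool_kinetics_step(st, pools.replace(n_mobile_init=0),
                                    5e-5, rng)
        assert st.docked == pools.n_docked_init
        assert st.n_total == pools.n_docked_init

    def test_vesicle_conservation_through_recycling(self, pools, rng):
        st = initial_release_state(pools)
        st.docked -= 5
        st.kr_fused += 3
        st.ff_fused += 2
        total = st.n_total
        for _ in range(5000):
            st = pool_kinetics_step(st, pools, 5e-5, rng)
            assert st.n_total == total
        # recycled vesicles eventually re-dock up to capacity
        assert st.kr_endocytosed + st.ff_endocytosed <= 5


class TestClampedCharacterization:
    def test_zero_calcium_gives_flat_zero_rates(self, sensors, pools):
        out = characterize_clamped(sensors, [0.0], pools, duration=0.5,
                                   n_points=200)
        assert np.all(out["kr_rate"] == 0.0)
        assert np.all(out["ff_rate"] == 0.0)

    def test_syt4_faster_than_syt7_at_high_calcium(self, sensors, pools):
        # mode separation: kiss-and-run (Syt4) peaks before full fusion
        # (Syt7) when Ca2+ is clamped far above both affinities
        out = characterize_clamped(sensors, [100.0], pools, duration=2.0)
        assert out["kr_time_to_peak"][0] < out["ff_time_to_peak"][0]
        assert out["kr_peak"][0] > out["ff_peak"][0]

    def test_syt4_time_to_peak_shrinks_with_calcium(self, sensors, pools):
        out = characterize_clamped(sensors, [5.0, 20.0, 80.0], pools,
                                   duration=1.0)
        ttp = out["kr_time_to_peak"]
        assert ttp[0] > ttp[1] > ttp[2]

    def test_empty_levels_rejected(self, sensors, pools):
        with pytest.raises(ValueError):
            characterize_clamped(sensors, [], pools)
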