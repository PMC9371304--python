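"""Compartment fluxes, resting state, and integration accuracy."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gliosim import ip3r
from gliosim.engine import SimulationConfig, run_trial
from gliosim.parameters import ModelParameters
from gliosim.signaling import (CompartmentState, continuous_rhs, flux_terms,
                               resting_state, step_compartment)
from gliosim.stimulus import StimulusProtocol


class TestRestingState:
    def test_all_net_fluxes_vanish(self, params):
        rest = resting_state(params)
        pf = (ip3r.stationary_distribution(rest.ca_cyt, rest.ip3, params)
              [ip3r.OPEN_SUBUNIT_STATE] ** 3)
        dydt = continuous_rhs(rest, params, open_fraction=pf)
        assert np.abs(dydt).max() < 1e-6

    def test_rest_is_subthreshold_and_er_loaded(self, params):
        rest = resting_state(params)
        assert rest.ca_cyt < 0.3          # below the event threshold
        assert rest.ca_er > rest.ca_cyt   # luminal store loaded

    def test_unstable_parameters_raise(self, params):
        bad = params.replace(pm_leak=params.pmca_vmax * 2)
        with pytest.raises(RuntimeError, match="unstable|fixed point"):
            resting_state(bad)

    def test_abeta_pmca_rest_elevated(self, params):
        from gliosim.abeta import apply_condition
        from gliosim.parameters import ConditionSpec
        rest = resting_state(params)
        rest_ab = resting_state(apply_condition(params,
                                                ConditionSpec(False, True)))
        assert rest_ab.ca_cyt > rest.ca_cyt
        assert rest_ab.ca_er > rest.ca_er


class TestFluxTerms:
    def test_pumps_idle_without_calcium(self, params):
        st = CompartmentState(0.0, 0.0, 200.0, 0.1, 0.0, 500.0,
                              np.zeros((params.n_ip3r, 3), dtype=np.int8))
        f = flux_terms(st, params)
        assert f["pmca"] == 0.0
        assert f["serca"] == 0.0
        assert f["plcd_ip3"] == 0.0

    def test_negative_concentration_rejected(self, params):
        st = CompartmentState(0.0, -0.1, 200.0, 0.1, 0.0, 500.0,
                              np.zeros((params.n_ip3r, 3), dtype=np.int8))
        with pytest.raises(ValueError, match="negative"):
            flux_terms(st, params)

    def test_mglur_production_saturates(self, params):
        st = resting_state(params)
        lo = flux_terms(st, params, glu=1.0)["mglur_ip3"]
        hi = flux_terms(st, params, glu=1e4)["mglur_ip3"]
        assert lo < hi <= params.mglur_vmax


class TestMassConservation:
    def test_total_calcium_conserved_without_membrane_fluxes(self, params):
        # with PMCA and the plasma-membrane leak (numerically) disabled, the
        # cytosol/buffer/ER ledger must close over the simulated interval
        closed = params.replace(pmca_vmax=1e-12, pm_leak=1e-12)
        rest = resting_state(params)  # deliberately NOT a fixed point now
        rho = params.er_cyt_volume_ratio

        def total(y):
            c, ce, p, bc, be = y
            return c + bc + rho * (ce + be)

        y = rest.continuous_vector()
        st = rest
        dt = 5e-5
        t0 = total(y)
        for _ in range(4000):  # 0.2 s
            pf = 0.05  # clamp channels partly open to force ER exchange
            dydt = continuous_rhs(st, closed, open_fraction=pf)
            y = y + dt * dydt
            st = CompartmentState(st.time_s + dt, *y, st.channel_states)
        assert total(y) == pytest.approx(t0, rel=1e-9)


class TestStepCompartment:
    def test_quiescent_run_stays_near_rest(self, params, rng):
        rest = resting_state(params)
        st = rest
        for _ in range(2000):  # 0.1 s
            st = step_compartment(st, params, 0.0, 0.0, 5e-5, rng)
        assert st.ca_cyt == pytest.approx(rest.ca_cyt, rel=0.05)
        assert st.ca_er == pytest.approx(rest.ca_er, rel=0.01)

    def test_nonfinite_flux_aborts(self, params, rng):
        st = CompartmentState(0.0, 1e308, 1e308, 0.1, 0.0, 0.0,
                              np.zeros((params.n_ip3r, 3), dtype=np.int8))
        with pytest.raises(FloatingPointError):
            step_compartment(st, params, 0.0, 0.0, 5e-5, rng)


class TestDeterministicAccuracy:
    def test_fixed_step_peak_ip3_matches_adaptive_reference(self, params):
        # 100 uM agonist clamp: the 50 us Euler mean-field trajectory must
        # agree with an adaptive high-accuracy integration of the identical
        # equations to < 1% on peak IP3.
        proto = StimulusProtocol(kind="agonist-pulse", agonist_conc_uM=100.0,
                                 agonist_onset_s=0.0, agonist_duration_s=2.0)
        cfg = SimulationConfig(protocol=proto, n_trials=1, duration_s=2.0,
                               record_stride=20)
        tr = run_trial(cfg, 0, stochastic=False)
        peak_fixed = tr.trace["ip3_uM"].max()

        p = cfg.params
        rest = resting_state(p)
        x0 = ip3r.stationary_distribution(rest.ca_cyt, rest.ip3, p)

        def rhs(t, y):
            st = CompartmentState(t, *np.clip(y[:5], 0, None),
                                  rest.channel_states)
            x = y[5:]
            pf = max(x[ip3r.OPEN_SUBUNIT_STATE], 0.0) ** 3
            dy = continuous_rhs(st, p, glu=0.0, agonist=100.0,
                                open_fraction=pf)
            Q = ip3r.subunit_rate_matrix(max(y[0], 0), max(y[2], 0), p)
            return np.concatenate([dy, Q.T @ x])

        y0 = np.concatenate([rest.continuous_vector(), x0])
        sol = solve_ivp(rhs, (0, 2.0), y0, method="LSODA", rtol=1e-8,
                        atol=1e-10, dense_output=True)
        peak_ref = sol.y[2].max()
        assert peak_fixed == pytest.approx(peak_ref, rel=0.01)

    def test_event_statistics_stable_when_halving_dt(self):
        # fixed-step artifacts would shift the event rate when the step
        # is refined; counts must agree within Monte-Carlo error
        from gliosim.events import detect_ca_events
        proto = StimulusProtocol(kind="agonist-pulse", agonist_conc_uM=100.0,
                                 agonist_onset_s=0.5, agonist_duration_s=2.0)
        counts = {}
        for dt in (5e-5, 2.5e-5):
            stride = int(round(1e-3 / dt))
            cfg = SimulationConfig(protocol=proto, n_trials=15, base_seed=42,
                                   duration_s=4.0, dt=dt,
                                   record_stride=stride)
            counts[dt] = np.array([
                len(detect_ca_events(
                    run_trial(cfg, i).trace["ca_cyt_uM"].to_numpy(), 1e-3))
                for i in range(15)])
        a, b = counts[5e-5], counts[2.5e-5]
        sem = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(a.mean() - b.mean()) <= 3 * sem + 1.0

    def test_peak_ip3_monotone_in_dose(self, params):
        from gliosim.abeta import ip3_dose_response
        doses = np.array([5.0, 20.0, 80.0, 320.0])
        _, peaks = ip3_dose_response(ModelParameters(), doses)
        assert np.all(np.diff(peaks) >= -1e-12)
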