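"""Dual-sensor (Syt4/Syt7) gliotransmitter release machinery.

Syt4 is a single low-affinity, fast Ca2+ sensor driving kiss-and-run
(KR) fusion of docked vesicles; Syt7 carries five sequential
higher-affinity, slow sites and drives full fusion (FF) of mobile
vesicles from its fully bound state.  Sensor occupancies are tracked as
pool-level expectations (mean-field); stochasticity enters at the
release draw (rate x dt against a uniform variate, at most one release
per mode per step) and at the binomial pool transitions.

Released vesicles are endocytosed and reacidified on their own pathway
before rejoining the mobile pool; mobile vesicles dock while free
docking sites remain.  Total vesicle number is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import SensorParameters, VesiclePools

__all__ = [
    "ReleaseMachineryState",
    "initial_release_state",
    "sensor_update",
    "syt7_rate_matrix",
    "release_rates",
    "sample_release_events",
    "pool_kinetics_step",
    "characterize_clamped",
]


@dataclass
class ReleaseMachineryState:
    """Sensor occupancies, integer vesicle pool counts, and the event log."""

    syt4_bound: float                 # expected bound fraction, 0..1
    syt7_occupancy: np.ndarray        # distribution over 0..5 bound sites
    docked: int
    mobile: int
    kr_fused: int                     # released (KR), awaiting endocytosis
    kr_reacidifying: int
    ff_fused: int                     # released (FF), awaiting endocytosis
    ff_reacidifying: int
    event_times: list = field(default_factory=list)
    event_modes: list = field(default_factory=list)  # "KR" | "FF"

    @property
    def kr_endocytosed(self) -> int:
        """Vesicles on the kiss-and-run recycling pathway (not yet mobile)."""
        return self.kr_fused + self.kr_reacidifying

    @property
    def ff_endocytosed(self) -> int:
        return self.ff_fused + self.ff_reacidifying

    @property
    def n_total(self) -> int:
        return (self.docked + self.mobile + self.kr_endocytosed
                + self.ff_endocytosed)

    def validate(self) -> None:
        if not (0.0 - 1e-9 <= self.syt4_bound <= 1.0 + 1e-9):
            raise ValueError("Syt4 occupancy outside [0, 1]; dt too large")
        if abs(self.syt7_occupancy.sum() - 1.0) > 1e-6 or np.any(
                self.syt7_occupancy < -1e-9):
            raise ValueError("Syt7 occupancy is not a distribution; dt too large")
        for name in ("docked", "mobile", "kr_fused", "kr_reacidifying",
                     "ff_fused", "ff_reacidifying"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative vesicle count in {name}")

    def copy(self) -> "ReleaseMachineryState":
        return ReleaseMachineryState(
            self.syt4_bound, self.syt7_occupancy.copy(), self.docked,
            self.mobile, self.kr_fused, self.kr_reacidifying, self.ff_fused,
            self.ff_reacidifying, list(self.event_times),
            list(self.event_modes))


def initial_release_state(pools: VesiclePools) -> ReleaseMachineryState:
    occ = np.zeros(6)
    occ[0] = 1.0
    return ReleaseMachineryState(0.0, occ, pools.n_docked_init,
                                 pools.n_mobile_init, 0, 0, 0, 0)


def syt7_rate_matrix(ca: float, params: SensorParameters) -> np.ndarray:
    """Generator of the six-state sequential Syt7 binding chain (1/s).

    Binding from state j proceeds at (5-j)*kon*Ca; unbinding at
    j*koff*b**(j-1) with cooperativity factor b tightening successive
    sites.
    """
    n = params.n_syt7_sites
    Q = np.zeros((n + 1, n + 1))
    for j in range(n):
        Q[j, j + 1] = (n - j) * params.syt7_kon * ca
    for j in range(1, n + 1):
        Q[j, j - 1] = j * params.syt7_koff * params.syt7_cooperativity ** (j - 1)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def sensor_update(state: ReleaseMachineryState, ca: float,
                  params: SensorParameters, dt: float) -> ReleaseMachineryState:
    """One explicit Euler step of both sensors' master equations at clamped Ca."""
    new = state.copy()
    s4 = state.syt4_bound
    new.syt4_bound = s4 + dt * (params.syt4_kon * ca * (1.0 - s4)
                                - params.syt4_koff * s4)
    Q = syt7_rate_matrix(ca, params)
    new.syt7_occupancy = state.syt7_occupancy + dt * (Q.T @ state.syt7_occupancy)
    new.validate()
    return new


def release_rates(state: ReleaseMachineryState,
                  params: SensorParameters) -> tuple[float, float]:
    """(KR, FF) instantaneous release rates (1/s).

    KR rate = Syt4 fusion rate x bound fraction x docked count;
    FF rate = Syt7 fusion rate x fully bound probability x mobile count.
    """
    kr = params.syt4_fusion_rate * max(state.syt4_bound, 0.0) * state.docked
    ff = params.syt7_fusion_rate * max(state.syt7_occupancy[-1], 0.0) * state.mobile
    return kr, ff


def sample_release_events(state: ReleaseMachineryState,
                          rates: tuple[float, float], dt: float,
                          rng: np.random.Generator,
                          time_s: float = 0.0) -> ReleaseMachineryState:
    """Draw at most one release per mode: release iff rate*dt > U(0,1)."""
    kr_rate, ff_rate = rates
    if kr_rate * dt >= 1.0 or ff_rate * dt >= 1.0:
        raise ValueError("release rate * dt must stay below 1; reduce dt")
    new = state.copy()
    t = time_s
    if kr_rate * dt > rng.random() and new.docked > 0:
        new.docked -= 1
        new.kr_fused += 1
        new.event_times.append(t)
        new.event_modes.append("KR")
    if ff_rate * dt > rng.random() and new.mobile > 0:
        new.mobile -= 1
        new.ff_fused += 1
        new.event_times.append(t)
        new.event_modes.append("FF")
    return new


def pool_kinetics_step(state: ReleaseMachineryState, pools: VesiclePools,
                       dt: float, rng: np.random.Generator
                       ) -> ReleaseMachineryState:
    """Binomial per-step recycling transitions; conserves total vesicles.

    fused -> reacidifying (pathway endocytosis rate), reacidifying ->
    mobile (pathway reacidification rate), mobile -> docked (docking
    rate, gated by free docking sites).
    """
    new = state.copy()
    kr_endo = rng.binomial(new.kr_fused, -np.expm1(-pools.kr_endo_rate * dt))
    ff_endo = rng.binomial(new.ff_fused, -np.expm1(-pools.ff_endo_rate * dt))
    kr_rea = rng.binomial(new.kr_reacidifying,
                          -np.expm1(-pools.kr_reacid_rate * dt))
    ff_rea = rng.binomial(new.ff_reacidifying,
                          -np.expm1(-pools.ff_reacid_rate * dt))
    free_sites = max(pools.docked_capacity - new.docked, 0)
    dock = min(rng.binomial(new.mobile, -np.expm1(-pools.docking_rate * dt)),
               free_sites)
    new.kr_fused -= kr_endo
    new.kr_reacidifying += kr_endo - kr_rea
    new.ff_fused -= ff_endo
    new.ff_reacidifying += ff_endo - ff_rea
    new.mobile += kr_rea + ff_rea - dock
    new.docked += dock
    assert new.n_total == state.n_total
    return new


def characterize_clamped(params: SensorParameters, ca_levels,
                         pools: VesiclePools | None = None,
                         duration: float = 2.0, n_points: int = 4000):
    """Deterministic expected release-rate time courses at clamped Ca2+.

    Starting from fully unbound sensors and full pools, integrates the
    coupled sensor master equations and the expected pool depletion
    (d docked/dt = -KR rate, d mobile/dt = -FF rate; replenishment off)
    for each clamped Ca2+ level.  Returns a dict with the time grid, the
    per-level KR/FF rate curves, and (peak rate, time-to-peak) tables.
    """
    ca_levels = np.atleast_1d(np.asarray(ca_levels, dtype=float))
    if ca_levels.size == 0:
        raise ValueError("ca_levels must be non-empty")
    if np.any(ca_levels < 0):
        raise ValueError("ca_levels must be non-negative")
    if pools is None:
        pools = VesiclePools()
    t_eval = np.linspace(0.0, duration, n_points)
    out = {
        "time_s": t_eval, "ca_uM": ca_levels,
        "kr_rate": np.zeros((ca_levels.size, n_points)),
        "ff_rate": np.zeros((ca_levels.size, n_points)),
        "kr_peak": np.zeros(ca_levels.size),
        "kr_time_to_peak": np.zeros(ca_levels.size),
        "ff_peak": np.zeros(ca_levels.size),
        "ff_time_to_peak": np.zeros(ca_levels.size),
    }
    n_s7 = params.n_syt7_sites
    for i, ca in enumerate(ca_levels):
        Q7 = syt7_rate_matrix(ca, params)

        def rhs(t, y):
            s4, docked, mobile = y[0], y[-2], y[-1]
            w = y[1:2 + n_s7]
            ds4 = params.syt4_kon * ca * (1 - s4) - params.syt4_koff * s4
            dw = Q7.T @ w
            d_docked = -params.syt4_fusion_rate * s4 * docked
            d_mobile = -params.syt7_fusion_rate * w[-1] * mobile
            return np.concatenate(([ds4], dw, [d_docked, d_mobile]))

        y0 = np.zeros(1 + (n_s7 + 1) + 2)
        y0[1] = 1.0
        y0[-2] = pools.n_docked_init
        y0[-1] = pools.n_mobile_init
        sol = solve_ivp(rhs, (0, duration), y0, t_eval=t_eval,
                        method="LSODA", rtol=1e-8, atol=1e-10)
        kr = params.syt4_fusion_rate * sol.y[0] * sol.y[-2]
        ff = params.syt7_fusion_rate * sol.y[1 + n_s7] * sol.y[-1]
        out["kr_rate"][i] = kr
        out["ff_rate"][i] = ff
        out["kr_peak"][i] = kr.max()
        out["kr_time_to_peak"][i] = t_eval[int(np.argmax(kr))]
        out["ff_peak"][i] = ff.max()
        out["ff_time_to_peak"][i] = t_eval[int(np.argmax(ff))]
    return out
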