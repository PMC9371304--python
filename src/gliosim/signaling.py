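"""Deterministic fluxes and state stepping for the Ca2+/IP3 compartment.

The compartment carries five continuous variables (cytosolic Ca2+, ER
Ca2+, IP3, and Ca2+ bound to the cytosolic and ER buffers, all uM) plus
the categorical states of the IP3R cluster.  Continuous variables evolve
by explicit Euler at a fixed step (50 us by default); channel gating is
the only stochastic ingredient, so the Euler-Maruyama update degenerates
to Euler plus Markov jumps.

ER fluxes are expressed as cytosolic concentration changes; what leaves
the ER enters the cytosol and vice versa, scaled by the ER/cytosol
volume ratio.  With pumps and plasma-membrane leak disabled, total Ca2+
(cytosol + cytosolic buffer + ratio * (ER + ER buffer)) is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import ip3r
from .parameters import ModelParameters

__all__ = [
    "DT_DEFAULT",
    "CompartmentState",
    "flux_terms",
    "continuous_rhs",
    "resting_state",
    "ip3r_transition_step",
    "step_compartment",
]

logger = logging.getLogger(__name__)

#: Global integration step (s): 50 us.
DT_DEFAULT = 5e-5

_CONTINUOUS = ("ca_cyt", "ca_er", "ip3", "buf_cyt_bound", "buf_er_bound")


@dataclass(frozen=True)
class CompartmentState:
    """Instantaneous state of the astrocytic compartment."""

    time_s: float
    ca_cyt: float       # uM
    ca_er: float        # uM
    ip3: float          # uM
    buf_cyt_bound: float  # uM
    buf_er_bound: float   # uM
    channel_states: np.ndarray  # (n_ip3r, 3) int8 subunit states

    def validate(self) -> None:
        for name in _CONTINUOUS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is negative")
        if np.any((self.channel_states < 0) | (self.channel_states > 7)):
            raise ValueError("channel subunit state outside 0..7")

    @property
    def n_open_channels(self) -> int:
        return ip3r.count_open_channels(self.channel_states)

    def continuous_vector(self) -> np.ndarray:
        return np.array([self.ca_cyt, self.ca_er, self.ip3,
                         self.buf_cyt_bound, self.buf_er_bound])

    def replace(self, **kw) -> "CompartmentState":
        return replace(self, **kw)


def flux_terms(state: CompartmentState, params: ModelParameters,
               glu: float = 0.0, agonist: float = 0.0,
               open_fraction: float | None = None) -> dict[str, float]:
    """Individually labeled flux contributions (uM/s, cytosolic scale).

    ``open_fraction`` overrides the fraction of open channels (used by the
    deterministic mean-field path); by default it is computed from the
    state's channel vector.
    """
    p = params
    c, ce, ip3_c = state.ca_cyt, state.ca_er, state.ip3
    if min(c, ce, ip3_c, state.buf_cyt_bound, state.buf_er_bound) < 0:
        raise ValueError("negative concentration in input state")
    if open_fraction is None:
        open_fraction = state.n_open_channels / p.n_ip3r
    c2 = c * c
    fluxes = {
        "ip3r": p.ip3r_flux_coeff * open_fraction * (ce - c),
        "er_leak": p.er_leak_rate * (ce - c),
        "serca": p.serca_vmax * c2 / (c2 + p.serca_kd ** 2),
        "pmca": p.pmca_vmax * c2 / (c2 + p.pmca_kb / p.pmca_kf),
        "pm_leak": p.pm_leak,
        "buf_cyt": p.buf_cyt_kon * c * (p.buf_cyt_total - state.buf_cyt_bound)
                   - p.buf_cyt_koff * state.buf_cyt_bound,
        "buf_er": p.buf_er_kon * ce * (p.buf_er_total - state.buf_er_bound)
                  - p.buf_er_koff * state.buf_er_bound,
        "mglur_ip3": _mglur_production(glu + agonist, p),
        "plcd_ip3": p.plcd_vmax * c2 / (c2 + p.plcd_kd ** 2),
        "ip3_5p": p.ip3_5p_rate * ip3_c,
        "ip3_3k": p.ip3_3k_rate * c2 / (c2 + p.ip3_3k_kd ** 2) * ip3_c,
    }
    return fluxes


def _mglur_production(agonist: float, p: ModelParameters) -> float:
    if agonist <= 0:
        return 0.0
    a = agonist ** p.mglur_hill
    return p.mglur_vmax * a / (a + p.mglur_kd ** p.mglur_hill)


def continuous_rhs(state: CompartmentState, params: ModelParameters,
                   glu: float = 0.0, agonist: float = 0.0,
                   open_fraction: float | None = None) -> np.ndarray:
    """Time derivatives (uM/s) of the five continuous variables."""
    f = flux_terms(state, params, glu, agonist, open_fraction)
    er_net = f["ip3r"] + f["er_leak"] - f["serca"]  # ER -> cytosol, cytosolic scale
    d_ca = er_net + f["pm_leak"] - f["pmca"] - f["buf_cyt"]
    d_er = -er_net / params.er_cyt_volume_ratio - f["buf_er"]
    d_ip3 = f["mglur_ip3"] + f["plcd_ip3"] - f["ip3_5p"] - f["ip3_3k"]
    return np.array([d_ca, d_er, d_ip3, f["buf_cyt"], f["buf_er"]])


def _reduced_residual(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    c, ce, ip3_c, bc, be = y
    st = CompartmentState(0.0, max(c, 0.0), max(ce, 0.0), max(ip3_c, 0.0),
                          max(bc, 0.0), max(be, 0.0),
                          np.zeros((params.n_ip3r, 3), dtype=np.int8))
    pi = ip3r.stationary_distribution(max(c, 1e-9), max(ip3_c, 1e-9), params)
    pf = float(pi[ip3r.OPEN_SUBUNIT_STATE]) ** ip3r.SUBUNITS_PER_CHANNEL
    return continuous_rhs(st, params, open_fraction=pf)


def resting_state(params: ModelParameters, tol: float = 1e-8) -> CompartmentState:
    """Fixed point of the deterministic fluxes with channels at stationarity.

    Solves for the concentrations at which every net deterministic flux
    vanishes, with the IP3R cluster at the stationary distribution for
    the resting Ca2+/IP3, then draws no channels (they are assigned their
    modal stationary sample deterministically via expected occupancies;
    stochastic runs re-sample from the stationary law).

    Raises ``RuntimeError`` if the fixed-point search does not converge,
    which signals an unstable parameter set.
    """
    params.validate()
    p = params
    # The rest point decouples: plasma-membrane balance fixes Ca_cyt,
    # the IP3 balance then fixes IP3, and the ER balance fixes Ca_ER.
    if p.pm_leak >= p.pmca_vmax:
        raise RuntimeError(
            "membrane leak exceeds PMCA capacity: no resting fixed point "
            "(unstable parameter set)")
    k2 = p.pmca_kb / p.pmca_kf
    c = float(np.sqrt(p.pm_leak * k2 / (p.pmca_vmax - p.pm_leak)))
    c2 = c * c
    prod = p.plcd_vmax * c2 / (c2 + p.plcd_kd ** 2)
    deg_rate = p.ip3_5p_rate + p.ip3_3k_rate * c2 / (c2 + p.ip3_3k_kd ** 2)
    ip3_c = prod / deg_rate
    po = float(ip3r.stationary_distribution(c, ip3_c, params)
               [ip3r.OPEN_SUBUNIT_STATE] ** ip3r.SUBUNITS_PER_CHANNEL)
    serca = p.serca_vmax * c2 / (c2 + p.serca_kd ** 2)
    ce = c + serca / (p.ip3r_flux_coeff * po + p.er_leak_rate)
    bc = p.buf_cyt_total * c / (c + p.buf_cyt_koff / p.buf_cyt_kon)
    be = p.buf_er_total * ce / (ce + p.buf_er_koff / p.buf_er_kon)
    resid = np.abs(_reduced_residual(np.array([c, ce, ip3_c, bc, be]), params))
    if resid.max() > max(tol, 1e-6):
        raise RuntimeError(
            f"resting-state residual {resid.max():.3g} exceeds tolerance; "
            "parameter set appears unstable")
    pi = ip3r.stationary_distribution(c, ip3_c, params)
    # Deterministic representative channel configuration: assign subunits to
    # their stationary law by quantile (stochastic callers re-sample).
    counts = np.round(pi * params.n_ip3r * 3).astype(int)
    while counts.sum() > params.n_ip3r * 3:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < params.n_ip3r * 3:
        counts[np.argmax(pi)] += 1
    flat = np.repeat(np.arange(8, dtype=np.int8), counts)
    return CompartmentState(0.0, c, ce, ip3_c, bc, be,
                            flat.reshape(params.n_ip3r, 3))


def ip3r_transition_step(state: CompartmentState, params: ModelParameters,
                         dt: float, rng: np.random.Generator) -> CompartmentState:
    """Advance only the channel Markov states by one step (see :mod:`gliosim.ip3r`)."""
    new = ip3r.transition_step(state.channel_states, state.ca_cyt, state.ip3,
                               params, dt, rng)
    return state.replace(channel_states=new)


def step_compartment(state: CompartmentState, params: ModelParameters,
                     glu: float, agonist: float, dt: float,
                     rng: np.random.Generator) -> CompartmentState:
    """One fixed-step update: explicit Euler on fluxes + channel Markov jumps.

    Concentrations are clipped at zero with a logged warning if an Euler
    excursion undershoots; NaN/Inf aborts the run with a diagnostic.
    """
    dydt = continuous_rhs(state, params, glu, agonist)
    if not np.all(np.isfinite(dydt)):
        names = ("ca_cyt", "ca_er", "ip3", "buf_cyt_bound", "buf_er_bound")
        bad = [n for n, v in zip(names, dydt) if not np.isfinite(v)]
        raise FloatingPointError(
            f"non-finite flux for {bad} at t={state.time_s:.6f}s")
    y = state.continuous_vector() + dt * dydt
    if np.any(y < 0):
        logger.warning("negative-concentration excursion clipped at t=%.6f s",
                       state.time_s)
        y = np.clip(y, 0.0, None)
    new_channels = ip3r.transition_step(state.channel_states, state.ca_cyt,
                                        state.ip3, params, dt, rng)
    return CompartmentState(state.time_s + dt, *y, new_channels)
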