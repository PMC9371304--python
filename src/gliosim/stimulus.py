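"""Stimulus protocols: bath agonist (DHPG) pulses and presynaptic glutamate trains.

Each presynaptic spike deposits an instantaneous glutamate pulse of
amplitude ``glu_max`` (~200 uM) into the perisynaptic space, which then
decays first-order with rate ``k_glu`` (default 1/6.25 ms, absorbing
receptor binding and reuptake).  Bath agonist pulses are rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StimulusProtocol",
    "GlutamateState",
    "spike_times",
    "glutamate_concentration_step",
    "glutamate_trace",
    "agonist_concentration",
]

#: Default glutamate pulse amplitude following one presynaptic spike (uM).
GLU_MAX_DEFAULT = 200.0
#: Default glutamate decay rate constant, 1/(6.25 ms) (1/s).
K_GLU_DEFAULT = 160.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Declarative description of the stimulation applied to one compartment.

    ``kind`` is ``"agonist-pulse"`` (rectangular DHPG application) or
    ``"glutamate-train"`` (presynaptic spikes at ``rate_hz`` for
    ``train_duration_s``, regular or Poisson timing).
    """

    kind: str = "agonist-pulse"
    # agonist pulse
    agonist_conc_uM: float = 100.0
    agonist_onset_s: float = 1.0
    agonist_duration_s: float = 2.0
    # glutamate train
    rate_hz: float = 10.0
    train_onset_s: float = 1.0
    train_duration_s: float = 11.0
    timing: str = "regular"  # or "poisson"
    glu_max_uM: float = GLU_MAX_DEFAULT
    k_glu_per_s: float = K_GLU_DEFAULT
    glu_baseline_uM: float = 0.0

    def validate(self) -> None:
        if self.kind not in ("agonist-pulse", "glutamate-train", "none"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "glutamate-train":
            if self.rate_hz <= 0:
                raise ValueError("spike rate must be positive")
            if not (0.4 <= self.rate_hz <= 100.0):
                raise ValueError("train rate outside the supported 0.4-100 Hz sweep")
            if self.timing not in ("regular", "poisson"):
                raise ValueError(f"unknown spike timing mode {self.timing!r}")
        if self.glu_max_uM <= 0 or self.k_glu_per_s <= 0:
            raise ValueError("glu_max_uM and k_glu_per_s must be positive")
        if self.glu_baseline_uM < 0:
            raise ValueError("baseline glutamate cannot be negative")

    def replace(self, **kw) -> "StimulusProtocol":
        return replace(self, **kw)

    @property
    def stimulus_window(self) -> tuple[float, float]:
        """(onset, offset) of the stimulation epoch in seconds."""
        if self.kind == "agonist-pulse":
            return (self.agonist_onset_s,
                    self.agonist_onset_s + self.agonist_duration_s)
        if self.kind == "glutamate-train":
            return (self.train_onset_s,
                    self.train_onset_s + self.train_duration_s)
        return (0.0, 0.0)


@dataclass
class GlutamateState:
    """Instantaneous glutamate concentration plus pending spike times."""

    conc_uM: float = 0.0
    pending_spikes: np.ndarray = None  # strictly increasing times (s)
    time_s: float = 0.0

    def __post_init__(self):
        if self.pending_spikes is None:
            self.pending_spikes = np.empty(0)
        if self.conc_uM < 0:
            raise ValueError("glutamate concentration cannot be negative")


def spike_times(protocol: StimulusProtocol, rng: np.random.Generator | None = None
                ) -> np.ndarray:
    """Presynaptic spike times (s) for a glutamate-train protocol.

    Regular mode places spikes at k/rate from the train onset; Poisson
    mode draws exponential inter-spike intervals at the same rate.  The
    returned array is strictly increasing and confined to the train window.
    """
    protocol.validate()
    if protocol.kind != "glutamate-train":
        raise ValueError("spike_times requires a glutamate-train protocol")
    t0, dur, rate = (protocol.train_onset_s, protocol.train_duration_s,
                     protocol.rate_hz)
    if protocol.timing == "regular":
        n = int(np.floor(dur * rate - 1e-12)) + 1
        times = t0 + np.arange(n) / rate
        return times[times < t0 + dur]
    if rng is None:
        raise ValueError("Poisson spike timing requires an rng")
    times = []
    t = t0 + rng.exponential(1.0 / rate)
    while t < t0 + dur:
        times.append(t)
        t += rng.exponential(1.0 / rate)
    return np.asarray(times)


def glutamate_concentration_step(state: GlutamateState, dt: float,
                                 protocol: StimulusProtocol) -> GlutamateState:
    """Advance the glutamate concentration by one time step.

    Any pending spike inside (t, t+dt] adds ``glu_max`` instantaneously;
    between spikes the concentration relaxes first-order toward baseline.
    """
    t_next = state.time_s + dt
    conc = state.conc_uM
    base = protocol.glu_baseline_uM
    conc = base + (conc - base) * np.exp(-protocol.k_glu_per_s * dt)
    fired = (state.pending_spikes > state.time_s) & (state.pending_spikes <= t_next)
    conc += protocol.glu_max_uM * int(fired.sum())
    return GlutamateState(conc_uM=max(conc, 0.0),
                          pending_spikes=state.pending_spikes[state.pending_spikes > t_next],
                          time_s=t_next)


def glutamate_trace(spikes: np.ndarray, t: np.ndarray,
                    protocol: StimulusProtocol) -> np.ndarray:
    """Closed-form glutamate trace: superposition of single-spike exponentials."""
    glu = np.full_like(t, float(protocol.glu_baseline_uM))
    for ts in np.atleast_1d(spikes):
        mask = t >= ts
        glu[mask] += protocol.glu_max_uM * np.exp(
            -protocol.k_glu_per_s * (t[mask] - ts))
    return glu


def agonist_concentration(protocol: StimulusProtocol, t) -> np.ndarray | float:
    """Bath agonist (DHPG) concentration at time(s) ``t`` for a pulse protocol."""
    if protocol.kind != "agonist-pulse":
        return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
    t = np.asarray(t, dtype=float)
    on = protocol.agonist_onset_s
    inside = (t >= on) & (t < on + protocol.agonist_duration_s)
    out = np.where(inside, protocol.agonist_conc_uM, 0.0)
    return out if out.ndim else float(out)
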