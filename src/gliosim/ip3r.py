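"""Eight-state IP3 receptor subunit gating (De Young-Keizer scheme).

Each IP3R subunit carries one IP3 site, one activating Ca2+ site, and one
inhibitory Ca2+ site.  Subunit state is encoded as an integer 0..7 with
bits (i, j, k): i = IP3 bound (bit 2), j = activating Ca2+ bound (bit 1),
k = inhibitory Ca2+ bound (bit 0).  A channel consists of three
independent subunits and conducts when all three occupy the active state
(i=1, j=1, k=0), i.e. state index 6.

Rate constants follow the a1..a5 / b1..b5 naming: a1/b1 IP3 binding with
inhibition site empty, a3/b3 with it occupied; a2/b2 inhibitory Ca2+
binding with IP3 bound, a4/b4 without; a5/b5 activating Ca2+ binding.
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "OPEN_SUBUNIT_STATE",
    "N_SUBUNIT_STATES",
    "SUBUNITS_PER_CHANNEL",
    "subunit_rate_matrix",
    "stationary_distribution",
    "open_probability",
    "sample_stationary_states",
    "transition_step",
]

OPEN_SUBUNIT_STATE = 6  # (i=1, j=1, k=0)
N_SUBUNIT_STATES = 8
SUBUNITS_PER_CHANNEL = 3


def subunit_rate_matrix(ca: float, ip3: float, params: ModelParameters) -> np.ndarray:
    """Generator matrix Q (8x8, 1/s) of one subunit at clamped Ca2+/IP3.

    Q[s, s'] is the transition rate from state s to s'; rows sum to zero.
    """
    p = params
    Q = np.zeros((8, 8))
    for s in range(8):
        i, j, k = (s >> 2) & 1, (s >> 1) & 1, s & 1
        # IP3 site
        if i == 0:
            Q[s, s + 4] = (p.ip3r_a1 if k == 0 else p.ip3r_a3) * ip3
        else:
            Q[s, s - 4] = p.ip3r_b1 if k == 0 else p.ip3r_b3
        # inhibitory Ca site
        if k == 0:
            Q[s, s + 1] = (p.ip3r_a2 if i == 1 else p.ip3r_a4) * ca
        else:
            Q[s, s - 1] = p.ip3r_b2 if i == 1 else p.ip3r_b4
        # activating Ca site
        if j == 0:
            Q[s, s + 2] = p.ip3r_a5 * ca
        else:
            Q[s, s - 2] = p.ip3r_b5
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(ca: float, ip3: float, params: ModelParameters) -> np.ndarray:
    """Stationary occupancy of the subunit chain (null space of Q^T)."""
    Q = subunit_rate_matrix(ca, ip3, params)
    # Solve pi Q = 0 with sum(pi) = 1 via a bordered linear system.
    A = np.vstack([Q.T, np.ones(8)])
    b = np.zeros(9)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def open_probability(ca: float, ip3: float, params: ModelParameters) -> float:
    """Stationary probability that a three-subunit channel conducts."""
    return float(stationary_distribution(ca, ip3, params)[OPEN_SUBUNIT_STATE]
                 ** SUBUNITS_PER_CHANNEL)


def sample_stationary_states(ca: float, ip3: float, params: ModelParameters,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw subunit states (n_ip3r x 3 int8 array) from the stationary law."""
    pi = stationary_distribution(ca, ip3, params)
    return rng.choice(8, size=(params.n_ip3r, SUBUNITS_PER_CHANNEL),
                      p=pi).astype(np.int8)


def transition_step(states: np.ndarray, ca: float, ip3: float,
                    params: ModelParameters, dt: float,
                    rng: np.random.Generator,
                    max_step_probability: float = 0.1) -> np.ndarray:
    """Advance every subunit by at most one Markov transition over dt.

    Exit rates are linear in the clamped Ca2+/IP3; a per-step transition
    probability above ``max_step_probability`` signals that dt is too
    large for the supplied rate constants.
    """
    Q = subunit_rate_matrix(ca, ip3, params)
    exit_prob = -np.diag(Q) * dt
    if exit_prob.max() > max_step_probability:
        raise ValueError(
            f"per-step transition probability {exit_prob.max():.3f} exceeds "
            f"{max_step_probability}; reduce dt")
    flat = states.ravel()
    u = rng.random(flat.size)
    new = flat.copy()
    for s in range(8):
        idx = np.nonzero(flat == s)[0]
        if idx.size == 0:
            continue
        targets = np.nonzero(Q[s] > 0)[0]
        cum = np.cumsum(Q[s, targets] * dt)
        for pos, upper in zip(targets, cum):
            lower = upper - Q[s, pos] * dt
            hit = idx[(u[idx] >= lower) & (u[idx] < upper)]
            new[hit] = pos
    return new.reshape(states.shape)


def count_open_channels(states: np.ndarray) -> int:
    """Number of channels whose three subunits are all in the active state."""
    return int(np.all(states == OPEN_SUBUNIT_STATE, axis=1).sum())
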