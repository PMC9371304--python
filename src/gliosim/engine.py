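"""Fixed-step simulation engine: seeded trials, batches, and export.

The inner loop advances the compartment at a fixed 50 us step with
explicit Euler for the continuous variables, per-subunit Markov jumps
for the IP3R cluster, mean-field sensor occupancies, uniform-variate
release draws, and binomial pool transitions.  It is compiled with
numba; a run is fully determined by (parameters, protocol, base seed,
trial index).

A mean-field (noise-free) mode replaces channel sampling by the
subunit master equation and expected-value pools; it backs the
deterministic dose-response characterizations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit

from . import ip3r
from .events import CA_EVENT_THRESHOLD, EventMatrix, detect_ca_events
from .parameters import (ConditionSpec, ModelParameters, SensorParameters,
                         VesiclePools, default_parameters)
from .signaling import DT_DEFAULT, resting_state
from .stimulus import StimulusProtocol, spike_times

__all__ = [
    "SimulationConfig",
    "TrialResult",
    "TrialBatchResult",
    "run_trial",
    "run_batch",
    "export_results",
    "import_results",
    "TRACE_COLUMNS",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("time_s", "ca_cyt_uM", "ca_er_uM", "ip3_uM", "glu_uM",
                 "n_open_channels", "docked", "mobile", "kr_endocytosed",
                 "ff_endocytosed", "syt4_bound", "syt7_full",
                 "buf_cyt_bound_uM", "buf_er_bound_uM")

# --- parameter vector layout for the compiled kernel -----------------------
_PK = dict(ratio=0, n_ip3r=1, a1=2, a2=3, a3=4, a4=5, a5=6, b1=7, b2=8, b3=9,
           b4=10, b5=11, nu=12, er_leak=13, serca_v=14, serca_k=15, pmca_v=16,
           pmca_k2=17, pm_leak=18, bc_tot=19, bc_on=20, bc_off=21, be_tot=22,
           be_on=23, be_off=24, mg_v=25, mg_k=26, mg_h=27, plc_v=28, plc_k=29,
           r5p=30, r3k=31, k3k=32, s4_on=33, s4_off=34, s4_fuse=35, s7_on=36,
           s7_off=37, s7_coop=38, s7_fuse=39, kr_endo=40, kr_rea=41,
           ff_endo=42, ff_rea=43, dock=44, dock_cap=45, glu_max=46, k_glu=47,
           glu_base=48)
_NPK = len(_PK)


def pack_params(mp: ModelParameters, sp: SensorParameters, vp: VesiclePools,
                protocol: StimulusProtocol) -> np.ndarray:
    pv = np.zeros(_NPK)
    pv[_PK["ratio"]] = mp.er_cyt_volume_ratio
    pv[_PK["n_ip3r"]] = mp.n_ip3r
    for n, key in zip(("a1", "a2", "a3", "a4", "a5", "b1", "b2", "b3", "b4",
                       "b5"),
                      ("ip3r_a1", "ip3r_a2", "ip3r_a3", "ip3r_a4", "ip3r_a5",
                       "ip3r_b1", "ip3r_b2", "ip3r_b3", "ip3r_b4", "ip3r_b5")):
        pv[_PK[n]] = getattr(mp, key)
    pv[_PK["nu"]] = mp.ip3r_flux_coeff
    pv[_PK["er_leak"]] = mp.er_leak_rate
    pv[_PK["serca_v"]] = mp.serca_vmax
    pv[_PK["serca_k"]] = mp.serca_kd
    pv[_PK["pmca_v"]] = mp.pmca_vmax
    pv[_PK["pmca_k2"]] = mp.pmca_kb / mp.pmca_kf
    pv[_PK["pm_leak"]] = mp.pm_leak
    pv[_PK["bc_tot"]] = mp.buf_cyt_total
    pv[_PK["bc_on"]] = mp.buf_cyt_kon
    pv[_PK["bc_off"]] = mp.buf_cyt_koff
    pv[_PK["be_tot"]] = mp.buf_er_total
    pv[_PK["be_on"]] = mp.buf_er_kon
    pv[_PK["be_off"]] = mp.buf_er_koff
    pv[_PK["mg_v"]] = mp.mglur_vmax
    pv[_PK["mg_k"]] = mp.mglur_kd
    pv[_PK["mg_h"]] = mp.mglur_hill
    pv[_PK["plc_v"]] = mp.plcd_vmax
    pv[_PK["plc_k"]] = mp.plcd_kd
    pv[_PK["r5p"]] = mp.ip3_5p_rate
    pv[_PK["r3k"]] = mp.ip3_3k_rate
    pv[_PK["k3k"]] = mp.ip3_3k_kd
    pv[_PK["s4_on"]] = sp.syt4_kon
    pv[_PK["s4_off"]] = sp.syt4_koff
    pv[_PK["s4_fuse"]] = sp.syt4_fusion_rate
    pv[_PK["s7_on"]] = sp.syt7_kon
    pv[_PK["s7_off"]] = sp.syt7_koff
    pv[_PK["s7_coop"]] = sp.syt7_cooperativity
    pv[_PK["s7_fuse"]] = sp.syt7_fusion_rate
    pv[_PK["kr_endo"]] = vp.kr_endo_rate
    pv[_PK["kr_rea"]] = vp.kr_reacid_rate
    pv[_PK["ff_endo"]] = vp.ff_endo_rate
    pv[_PK["ff_rea"]] = vp.ff_reacid_rate
    pv[_PK["dock"]] = vp.docking_rate
    pv[_PK["dock_cap"]] = vp.docked_capacity
    pv[_PK["glu_max"]] = protocol.glu_max_uM
    pv[_PK["k_glu"]] = protocol.k_glu_per_s
    pv[_PK["glu_base"]] = protocol.glu_baseline_uM
    return pv


@njit(cache=False)
def _kernel(pv, n_steps, dt, stride, seed, spike_steps, ag_conc, ag_on,
            ag_off, y0, ch0, x0, pools0, stochastic):  # pragma: no cover
    np.random.seed(seed)
    ratio = pv[0]
    n_ch = int(pv[1])
    a1, a2, a3, a4, a5 = pv[2], pv[3], pv[4], pv[5], pv[6]
    b1, b2, b3, b4, b5 = pv[7], pv[8], pv[9], pv[10], pv[11]
    nu, er_leak = pv[12], pv[13]
    serca_v, serca_k = pv[14], pv[15]
    pmca_v, pmca_k2 = pv[16], pv[17]
    pm_leak = pv[18]
    bc_tot, bc_on, bc_off = pv[19], pv[20], pv[21]
    be_tot, be_on, be_off = pv[22], pv[23], pv[24]
    mg_v, mg_k, mg_h = pv[25], pv[26], pv[27]
    plc_v, plc_k = pv[28], pv[29]
    r5p, r3k, k3k = pv[30], pv[31], pv[32]
    s4_on, s4_off, s4_fuse = pv[33], pv[34], pv[35]
    s7_on, s7_off, s7_coop, s7_fuse = pv[36], pv[37], pv[38], pv[39]
    kr_endo, kr_rea = pv[40], pv[41]
    ff_endo, ff_rea = pv[42], pv[43]
    dock_rate, dock_cap = pv[44], pv[45]
    glu_max, k_glu, glu_base = pv[46], pv[47], pv[48]

    c, ce, p, bc, be = y0[0], y0[1], y0[2], y0[3], y0[4]
    ch = ch0.copy()
    x = x0.copy()
    docked = float(pools0[0])
    mobile = float(pools0[1])
    kr_f, kr_r = float(pools0[2]), float(pools0[3])
    ff_f, ff_r = float(pools0[4]), float(pools0[5])
    s4 = 0.0
    w = np.zeros(6)
    w[0] = 1.0
    coop = np.empty(5)
    for j in range(5):
        coop[j] = s7_coop ** j

    glu = glu_base
    decay = np.exp(-k_glu * dt)

    n_rec = n_steps // stride + 1
    rec = np.zeros((n_rec, 14))
    cap = 60000
    ev_t = np.zeros(cap)
    ev_m = np.zeros(cap, dtype=np.int8)
    n_ev = 0
    n_clip = 0
    status = 0
    sp_i = 0
    rec_i = 0
    mg_kh = mg_k ** mg_h

    for step in range(n_steps):
        t = step * dt
        # --- stimulus ---------------------------------------------------
        glu = glu_base + (glu - glu_base) * decay
        while sp_i < spike_steps.size and spike_steps[sp_i] == step:
            glu += glu_max
            sp_i += 1
        ag = ag_conc if (step >= ag_on and step < ag_off) else 0.0

        # --- record (state at step start) -------------------------------
        if step % stride == 0:
            if stochastic:
                nopen = 0
                for ci in range(n_ch):
                    if ch[ci, 0] == 6 and ch[ci, 1] == 6 and ch[ci, 2] == 6:
                        nopen += 1
                fopen = nopen / n_ch
            else:
                fopen = x[6] ** 3
                nopen = fopen * n_ch
            rec[rec_i, 0] = t
            rec[rec_i, 1] = c
            rec[rec_i, 2] = ce
            rec[rec_i, 3] = p
            rec[rec_i, 4] = glu
            rec[rec_i, 5] = nopen
            rec[rec_i, 6] = docked
            rec[rec_i, 7] = mobile
            rec[rec_i, 8] = kr_f + kr_r
            rec[rec_i, 9] = ff_f + ff_r
            rec[rec_i, 10] = s4
            rec[rec_i, 11] = w[5]
            rec[rec_i, 12] = bc
            rec[rec_i, 13] = be
            rec_i += 1

        # --- fluxes ------------------------------------------------------
        if stochastic:
            nopen = 0
            for ci in range(n_ch):
                if ch[ci, 0] == 6 and ch[ci, 1] == 6 and ch[ci, 2] == 6:
                    nopen += 1
            fopen = nopen / n_ch
        else:
            fopen = x[6] ** 3
        c2 = c * c
        j_er = (nu * fopen + er_leak) * (ce - c) \
            - serca_v * c2 / (c2 + serca_k * serca_k)
        j_bc = bc_on * c * (bc_tot - bc) - bc_off * bc
        j_be = be_on * ce * (be_tot - be) - be_off * be
        agl = glu + ag
        if agl > 0.0:
            prod = mg_v * agl ** mg_h / (agl ** mg_h + mg_kh)
        else:
            prod = 0.0
        dc = j_er + pm_leak - pmca_v * c2 / (c2 + pmca_k2) - j_bc
        dce = -j_er / ratio - j_be
        dp = prod + plc_v * c2 / (c2 + plc_k * plc_k) \
            - (r5p + r3k * c2 / (c2 + k3k * k3k)) * p

        c_new = c + dt * dc
        ce_new = ce + dt * dce
        p_new = p + dt * dp
        bc_new = bc + dt * j_bc
        be_new = be + dt * j_be
        if c_new < 0.0:
            c_new = 0.0
            n_clip += 1
        if ce_new < 0.0:
            ce_new = 0.0
            n_clip += 1
        if p_new < 0.0:
            p_new = 0.0
            n_clip += 1
        if bc_new < 0.0:
            bc_new = 0.0
        if be_new < 0.0:
            be_new = 0.0
        if not (np.isfinite(c_new) and np.isfinite(ce_new)
                and np.isfinite(p_new)):
            status = 1
            break

        # --- IP3R gating (uses concentrations at step start) -------------
        if stochastic:
            for ci in range(n_ch):
                for si in range(3):
                    s = ch[ci, si]
                    i_b = (s >> 2) & 1
                    j_b = (s >> 1) & 1
                    k_b = s & 1
                    u = np.random.random()
                    acc = 0.0
                    # IP3 site
                    if i_b == 0:
                        r = (a1 if k_b == 0 else a3) * p
                        tgt = s + 4
                    else:
                        r = b1 if k_b == 0 else b3
                        tgt = s - 4
                    acc += r * dt
                    if u < acc:
                        ch[ci, si] = tgt
                        continue
                    # inhibitory Ca site
                    if k_b == 0:
                        r = (a2 if i_b == 1 else a4) * c
                        tgt = s + 1
                    else:
                        r = b2 if i_b == 1 else b4
                        tgt = s - 1
                    acc += r * dt
                    if u < acc:
                        ch[ci, si] = tgt
                        continue
                    # activating Ca site
                    if j_b == 0:
                        r = a5 * c
                        tgt = s + 2
                    else:
                        r = b5
                        tgt = s - 2
                    acc += r * dt
                    if u < acc:
                        ch[ci, si] = tgt
        else:
            dx = np.zeros(8)
            for s in range(8):
                xs = x[s]
                if xs <= 0.0:
                    continue
                i_b = (s >> 2) & 1
                j_b = (s >> 1) & 1
                k_b = s & 1
                if i_b == 0:
                    r = (a1 if k_b == 0 else a3) * p
                    tgt = s + 4
                else:
                    r = b1 if k_b == 0 else b3
                    tgt = s - 4
                dx[s] -= r * xs
                dx[tgt] += r * xs
                if k_b == 0:
                    r = (a2 if i_b == 1 else a4) * c
                    tgt = s + 1
                else:
                    r = b2 if i_b == 1 else b4
                    tgt = s - 1
                dx[s] -= r * xs
                dx[tgt] += r * xs
                if j_b == 0:
                    r = a5 * c
                    tgt = s + 2
                else:
                    r = b5
                    tgt = s - 2
                dx[s] -= r * xs
                dx[tgt] += r * xs
            for s in range(8):
                x[s] += dt * dx[s]
                if x[s] < 0.0:
                    x[s] = 0.0

        # --- sensors ------------------------------------------------------
        s4 += dt * (s4_on * c * (1.0 - s4) - s4_off * s4)
        if s4 < 0.0:
            s4 = 0.0
        elif s4 > 1.0:
            s4 = 1.0
        dw0 = -5.0 * s7_on * c * w[0] + s7_off * w[1]
        dw5 = s7_on * c * w[4] - 5.0 * s7_off * coop[4] * w[5]
        dw = np.empty(6)
        dw[0] = dw0
        for j in range(1, 5):
            dw[j] = ((6 - j) * s7_on * c * w[j - 1]
                     - ((5 - j) * s7_on * c + j * s7_off * coop[j - 1]) * w[j]
                     + (j + 1) * s7_off * coop[j] * w[j + 1])
        dw[5] = dw5
        for j in range(6):
            w[j] += dt * dw[j]
            if w[j] < 0.0:
                w[j] = 0.0

        # --- release ------------------------------------------------------
        kr_rate = s4_fuse * s4 * docked
        ff_rate = s7_fuse * w[5] * mobile
        if stochastic:
            if kr_rate * dt > np.random.random() and docked >= 1.0:
                docked -= 1.0
                kr_f += 1.0
                if n_ev < cap:
                    ev_t[n_ev] = t
                    ev_m[n_ev] = 0
                    n_ev += 1
            if ff_rate * dt > np.random.random() and mobile >= 1.0:
                mobile -= 1.0
                ff_f += 1.0
                if n_ev < cap:
                    ev_t[n_ev] = t
                    ev_m[n_ev] = 1
                    n_ev += 1
            # pool recycling (binomial thinning)
            mv = np.random.binomial(int(kr_f), 1.0 - np.exp(-kr_endo * dt))
            kr_f -= mv
            kr_r += mv
            mv = np.random.binomial(int(ff_f), 1.0 - np.exp(-ff_endo * dt))
            ff_f -= mv
            ff_r += mv
            mv = np.random.binomial(int(kr_r), 1.0 - np.exp(-kr_rea * dt))
            kr_r -= mv
            mobile += mv
            mv = np.random.binomial(int(ff_r), 1.0 - np.exp(-ff_rea * dt))
            ff_r -= mv
            mobile += mv
            free = int(dock_cap) - int(docked)
            if free > 0:
                mv = np.random.binomial(int(mobile),
                                        1.0 - np.exp(-dock_rate * dt))
                if mv > free:
                    mv = free
                mobile -= mv
                docked += mv
        else:
            d_rel_kr = kr_rate * dt
            d_rel_ff = ff_rate * dt
            docked -= d_rel_kr
            kr_f += d_rel_kr
            mobile -= d_rel_ff
            ff_f += d_rel_ff
            mv = kr_f * kr_endo * dt
            kr_f -= mv
            kr_r += mv
            mv = ff_f * ff_endo * dt
            ff_f -= mv
            ff_r += mv
            mv = kr_r * kr_rea * dt
            kr_r -= mv
            mobile += mv
            mv = ff_r * ff_rea * dt
            ff_r -= mv
            mobile += mv
            free = dock_cap - docked
            if free > 0.0:
                mv = mobile * dock_rate * dt
                if mv > free:
                    mv = free
                mobile -= mv
                docked += mv

        c, ce, p, bc, be = c_new, ce_new, p_new, bc_new, be_new

    # final record
    if stochastic:
        nopen = 0
        for ci in range(n_ch):
            if ch[ci, 0] == 6 and ch[ci, 1] == 6 and ch[ci, 2] == 6:
                nopen += 1
    else:
        nopen = x[6] ** 3 * n_ch
    if rec_i < n_rec:
        rec[rec_i, 0] = n_steps * dt
        rec[rec_i, 1] = c
        rec[rec_i, 2] = ce
        rec[rec_i, 3] = p
        rec[rec_i, 4] = glu
        rec[rec_i, 5] = nopen
        rec[rec_i, 6] = docked
        rec[rec_i, 7] = mobile
        rec[rec_i, 8] = kr_f + kr_r
        rec[rec_i, 9] = ff_f + ff_r
        rec[rec_i, 10] = s4
        rec[rec_i, 11] = w[5]
        rec[rec_i, 12] = bc
        rec[rec_i, 13] = be
        rec_i += 1
    return rec[:rec_i], ev_t[:n_ev], ev_m[:n_ev], status, n_clip


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a batch of trials."""

    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    condition: ConditionSpec = field(default_factory=ConditionSpec)
    n_trials: int = 1
    base_seed: int = 0
    dt: float = DT_DEFAULT
    duration_s: float = 11.0
    record_stride: int = 20        # record every stride-th step (1 ms default)
    params: ModelParameters | None = None
    sensors: SensorParameters | None = None
    pools: VesiclePools | None = None
    parameter_file: str | None = None
    out_dir: str | None = None
    out_format: str = "csv"

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        on, off = self.protocol.stimulus_window
        if self.duration_s < off:
            raise ValueError("duration must cover the stimulus extent")
        if self.params is None or self.sensors is None or self.pools is None:
            if self.parameter_file is not None:
                from .parameters import load_parameters
                mp, sp, vp = load_parameters(self.parameter_file)
            else:
                mp, sp, vp = default_parameters()
            from .abeta import apply_condition
            self.params = apply_condition(mp, self.condition) \
                if self.params is None else self.params
            self.sensors = sp if self.sensors is None else self.sensors
            self.pools = vp if self.pools is None else self.pools

    def config_hash(self) -> str:
        blob = json.dumps({
            "protocol": asdict(self.protocol),
            "condition": asdict(self.condition),
            "params": {k: v for k, v in asdict(self.params).items()
                       if k != "applied_conditions"},
            "sensors": asdict(self.sensors),
            "pools": asdict(self.pools),
            "n_trials": self.n_trials, "base_seed": self.base_seed,
            "dt": self.dt, "duration_s": self.duration_s,
            "record_stride": self.record_stride,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TrialResult:
    trial: int
    seed: int
    trace: pd.DataFrame
    release_times: np.ndarray
    release_modes: np.ndarray   # 0 = KR, 1 = FF
    n_clipped: int


@dataclass
class TrialBatchResult:
    config: SimulationConfig
    trials: list            # list[TrialResult]
    ca_events: EventMatrix
    kr_events: EventMatrix
    ff_events: EventMatrix
    seeds: list
    failures: list = field(default_factory=list)

    @property
    def release_events(self) -> EventMatrix:
        merged = [np.sort(np.concatenate([a, b])) for a, b in
                  zip(self.kr_events.trial_times, self.ff_events.trial_times)]
        return EventMatrix(merged, self.kr_events.rate_hz)


_REST_CACHE: dict = {}


def _resting(params: ModelParameters):
    key = tuple(v for k, v in sorted(asdict(params).items())
                if k != "applied_conditions")
    if key not in _REST_CACHE:
        _REST_CACHE[key] = resting_state(params)
    return _REST_CACHE[key]


def run_trial(config: SimulationConfig, trial_index: int,
              stochastic: bool = True) -> TrialResult:
    """Run one seeded trial; deterministic given (config, base seed, index)."""
    mp, sp, vp = config.params, config.sensors, config.pools
    proto = config.protocol
    proto.validate()
    seed = int(config.base_seed + trial_index) % (2 ** 31)
    rng = np.random.default_rng(seed)
    rest = _resting(mp)
    n_steps = int(round(config.duration_s / config.dt))
    if proto.kind == "glutamate-train":
        times = spike_times(proto, rng)
        spike_steps = np.asarray(np.round(times / config.dt), dtype=np.int64)
        ag_conc, ag_on, ag_off = 0.0, 0, 0
    else:
        spike_steps = np.empty(0, dtype=np.int64)
        if proto.kind == "agonist-pulse":
            ag_conc = proto.agonist_conc_uM
            ag_on = int(round(proto.agonist_onset_s / config.dt))
            ag_off = int(round((proto.agonist_onset_s
                                + proto.agonist_duration_s) / config.dt))
        else:
            ag_conc, ag_on, ag_off = 0.0, 0, 0
    y0 = rest.continuous_vector()
    if stochastic:
        ch0 = ip3r.sample_stationary_states(rest.ca_cyt, rest.ip3, mp, rng)
    else:
        ch0 = rest.channel_states
    x0 = ip3r.stationary_distribution(rest.ca_cyt, rest.ip3, mp)
    pools0 = np.array([vp.n_docked_init, vp.n_mobile_init, 0, 0, 0, 0],
                      dtype=np.int64)
    pv = pack_params(mp, sp, vp, proto)
    rec, ev_t, ev_m, status, n_clip = _kernel(
        pv, n_steps, config.dt, config.record_stride, seed, spike_steps,
        ag_conc, ag_on, ag_off, y0, np.ascontiguousarray(ch0, dtype=np.int8),
        x0, pools0, stochastic)
    if status != 0:
        raise FloatingPointError(
            f"trial {trial_index}: non-finite state encountered; aborting")
    if n_clip:
        logger.warning("trial %d: clipped %d negative-concentration excursions",
                       trial_index, n_clip)
    trace = pd.DataFrame(rec, columns=list(TRACE_COLUMNS))
    return TrialResult(trial_index, seed, trace, ev_t, ev_m.astype(int),
                       n_clip)


def run_batch(config: SimulationConfig, stochastic: bool = True,
              progress: bool = False) -> TrialBatchResult:
    """Run all trials independently (seeds base+index) and consolidate events.

    Partial failures are reported in ``failures`` without discarding
    completed trials.
    """
    trials, seeds, failures = [], [], []
    ca_lists, kr_lists, ff_lists = [], [], []
    sample_dt = config.dt * config.record_stride
    for idx in range(config.n_trials):
        try:
            tr = run_trial(config, idx, stochastic=stochastic)
        except Exception as exc:  # noqa: BLE001 - report, keep going
            failures.append((idx, repr(exc)))
            logger.error("trial %d failed: %s", idx, exc)
            continue
        trials.append(tr)
        seeds.append(tr.seed)
        recs = detect_ca_events(tr.trace["ca_cyt_uM"].to_numpy(), sample_dt,
                                trial=idx)
        ca_lists.append(np.array([r.t_peak for r in recs]))
        kr_lists.append(tr.release_times[tr.release_modes == 0])
        ff_lists.append(tr.release_times[tr.release_modes == 1])
        if progress:
            print(f"trial {idx + 1}/{config.n_trials}: "
                  f"{len(recs)} Ca events, "
                  f"{(tr.release_modes == 0).sum()} KR, "
                  f"{(tr.release_modes == 1).sum()} FF", flush=True)
    rate = config.protocol.rate_hz \
        if config.protocol.kind == "glutamate-train" else None
    return TrialBatchResult(config, trials,
                            EventMatrix(ca_lists, rate),
                            EventMatrix(kr_lists, rate),
                            EventMatrix(ff_lists, rate), seeds, failures)


_SUPPORTED_FORMATS = ("csv", "csv+traces")


def export_results(batch: TrialBatchResult, out_dir: str,
                   fmt: str = "csv") -> dict:
    """Write event tables (CSV) and a JSON provenance summary.

    ``csv+traces`` additionally writes one trace CSV per trial.  Returns
    the mapping of artifact names to paths; a round-trip through
    :func:`import_results` reproduces the event matrices exactly.
    """
    if fmt not in _SUPPORTED_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; supported: "
                         f"{_SUPPORTED_FORMATS}")
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (ca, kr, ff) in enumerate(zip(batch.ca_events.trial_times,
                                         batch.kr_events.trial_times,
                                         batch.ff_events.trial_times)):
        for t in ca:
            rows.append((i, t, "Ca"))
        for t in kr:
            rows.append((i, t, "KR"))
        for t in ff:
            rows.append((i, t, "FF"))
    events = pd.DataFrame(rows, columns=["trial", "time_s", "event_class"])
    events_path = os.path.join(out_dir, "events.csv")
    events.to_csv(events_path, index=False)
    summary = {
        "config_hash": batch.config.config_hash(),
        "base_seed": batch.config.base_seed,
        "n_trials": batch.config.n_trials,
        "trial_seeds": list(map(int, batch.seeds)),
        "condition": batch.config.condition.name,
        "dt": batch.config.dt,
        "duration_s": batch.config.duration_s,
        "protocol": asdict(batch.config.protocol),
        "failures": batch.failures,
        "n_ca_events": batch.ca_events.n_events,
        "n_kr_events": batch.kr_events.n_events,
        "n_ff_events": batch.ff_events.n_events,
    }
    summary_path = os.path.join(out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    paths = {"events": events_path, "summary": summary_path}
    if fmt == "csv+traces":
        for tr in batch.trials:
            path = os.path.join(out_dir, f"trace_{tr.trial:04d}.csv")
            tr.trace.to_csv(path, index=False)
            paths[f"trace_{tr.trial}"] = path
    return paths


def import_results(out_dir: str) -> tuple[dict, EventMatrix, EventMatrix,
                                          EventMatrix]:
    """Read back an exported batch: (summary, Ca, KR, FF event matrices)."""
    with open(os.path.join(out_dir, "summary.json")) as fh:
        summary = json.load(fh)
    events = pd.read_csv(os.path.join(out_dir, "events.csv"))
    n = summary["n_trials"]
    mats = {}
    for cls in ("Ca", "KR", "FF"):
        sub = events[events["event_class"] == cls]
        mats[cls] = EventMatrix([
            sub[sub["trial"] == i]["time_s"].to_numpy() for i in range(n)])
    return summary, mats["Ca"], mats["KR"], mats["FF"]
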