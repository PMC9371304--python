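"""Parameter containers for the astrocytic compartment model.

All concentrations are in uM, all times in seconds, all rates in 1/s or
1/(uM s) as documented in the bundled ``default_parameters.json``.  The
default values are versioned in that file; keys listed there under
``_calibrated`` were tuned against the published characterization targets
rather than taken from a primary source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict, replace
from importlib import resources
from typing import Iterable

__all__ = [
    "ModelParameters",
    "SensorParameters",
    "VesiclePools",
    "ConditionSpec",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "calibrated_keys",
]


def _load_default_dict() -> dict:
    with resources.files("gliosim.data").joinpath("default_parameters.json").open() as fh:
        return json.load(fh)


_DEFAULTS = _load_default_dict()


def calibrated_keys() -> list[str]:
    """Names of parameters whose default values are calibrated, not sourced."""
    return list(_DEFAULTS["_calibrated"])


@dataclass(frozen=True)
class ModelParameters:
    """Biophysical parameters of the Ca2+/IP3 signaling compartment.

    Covers compartment geometry, the eight-state IP3R gating scheme
    (one IP3 site, one activating and one inhibitory Ca2+ site per
    subunit; three subunits per channel, channel open when all three are
    in the active state), ER/plasma-membrane pumps and leaks, kinetic
    Ca2+ buffers in cytosol and ER, and the IP3 production/degradation
    pathways (mGluR, PLCdelta, 5-phosphatase, 3-kinase).
    """

    vol_cyt_um3: float = _DEFAULTS["model"]["vol_cyt_um3"]
    er_cyt_volume_ratio: float = _DEFAULTS["model"]["er_cyt_volume_ratio"]
    n_ip3r: int = _DEFAULTS["model"]["n_ip3r"]
    ip3r_a1: float = _DEFAULTS["model"]["ip3r_a1"]
    ip3r_a2: float = _DEFAULTS["model"]["ip3r_a2"]
    ip3r_a3: float = _DEFAULTS["model"]["ip3r_a3"]
    ip3r_a4: float = _DEFAULTS["model"]["ip3r_a4"]
    ip3r_a5: float = _DEFAULTS["model"]["ip3r_a5"]
    ip3r_b1: float = _DEFAULTS["model"]["ip3r_b1"]
    ip3r_b2: float = _DEFAULTS["model"]["ip3r_b2"]
    ip3r_b3: float = _DEFAULTS["model"]["ip3r_b3"]
    ip3r_b4: float = _DEFAULTS["model"]["ip3r_b4"]
    ip3r_b5: float = _DEFAULTS["model"]["ip3r_b5"]
    ip3r_flux_coeff: float = _DEFAULTS["model"]["ip3r_flux_coeff"]
    er_leak_rate: float = _DEFAULTS["model"]["er_leak_rate"]
    serca_vmax: float = _DEFAULTS["model"]["serca_vmax"]
    serca_kd: float = _DEFAULTS["model"]["serca_kd"]
    pmca_vmax: float = _DEFAULTS["model"]["pmca_vmax"]
    pmca_kf: float = _DEFAULTS["model"]["pmca_kf"]
    pmca_kb: float = _DEFAULTS["model"]["pmca_kb"]
    pm_leak: float = _DEFAULTS["model"]["pm_leak"]
    buf_cyt_total: float = _DEFAULTS["model"]["buf_cyt_total"]
    buf_cyt_kon: float = _DEFAULTS["model"]["buf_cyt_kon"]
    buf_cyt_koff: float = _DEFAULTS["model"]["buf_cyt_koff"]
    buf_er_total: float = _DEFAULTS["model"]["buf_er_total"]
    buf_er_kon: float = _DEFAULTS["model"]["buf_er_kon"]
    buf_er_koff: float = _DEFAULTS["model"]["buf_er_koff"]
    mglur_vmax: float = _DEFAULTS["model"]["mglur_vmax"]
    mglur_kd: float = _DEFAULTS["model"]["mglur_kd"]
    mglur_hill: float = _DEFAULTS["model"]["mglur_hill"]
    plcd_vmax: float = _DEFAULTS["model"]["plcd_vmax"]
    plcd_kd: float = _DEFAULTS["model"]["plcd_kd"]
    ip3_5p_rate: float = _DEFAULTS["model"]["ip3_5p_rate"]
    ip3_3k_rate: float = _DEFAULTS["model"]["ip3_3k_rate"]
    ip3_3k_kd: float = _DEFAULTS["model"]["ip3_3k_kd"]
    rest_ca_cyt: float = _DEFAULTS["model"]["rest_ca_cyt"]
    rest_ca_er: float = _DEFAULTS["model"]["rest_ca_er"]
    rest_ip3: float = _DEFAULTS["model"]["rest_ip3"]
    # Which pathology transforms have been applied (idempotency guard).
    applied_conditions: tuple = ()

    @property
    def pmca_kd(self) -> float:
        """Operational Ca2+ affinity of the PMCA pump, sqrt(kb/kf) (uM)."""
        return (self.pmca_kb / self.pmca_kf) ** 0.5

    def validate(self) -> None:
        positive = [
            f.name
            for f in fields(self)
            if f.name not in ("applied_conditions",)
        ]
        for name in positive:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {value}")
        if not (0 < self.er_cyt_volume_ratio <= 1):
            raise ValueError("er_cyt_volume_ratio must lie in (0, 1]")
        if self.n_ip3r < 1 or int(self.n_ip3r) != self.n_ip3r:
            raise ValueError("n_ip3r must be a positive integer")

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class SensorParameters:
    """Ca2+-binding kinetics of the two release sensors.

    Syt4 has a single low-affinity site (kd = koff/kon ~ 22 uM) with fast
    on-kinetics and drives kiss-and-run fusion of docked vesicles; Syt7
    carries five sequential higher-affinity sites (per-site kd ~ 15 uM,
    off-rates scaled by ``syt7_cooperativity`` per successive bound site)
    with slow on-kinetics and drives full fusion of mobile vesicles.
    """

    syt4_kon: float = _DEFAULTS["sensors"]["syt4_kon"]
    syt4_koff: float = _DEFAULTS["sensors"]["syt4_koff"]
    syt4_fusion_rate: float = _DEFAULTS["sensors"]["syt4_fusion_rate"]
    syt7_kon: float = _DEFAULTS["sensors"]["syt7_kon"]
    syt7_koff: float = _DEFAULTS["sensors"]["syt7_koff"]
    syt7_cooperativity: float = _DEFAULTS["sensors"]["syt7_cooperativity"]
    syt7_fusion_rate: float = _DEFAULTS["sensors"]["syt7_fusion_rate"]

    n_syt7_sites: int = 5

    @property
    def syt4_kd(self) -> float:
        return self.syt4_koff / self.syt4_kon

    @property
    def syt7_site_kd(self) -> float:
        return self.syt7_koff / self.syt7_kon

    def validate(self) -> None:
        for name in ("syt4_kon", "syt4_koff", "syt4_fusion_rate",
                     "syt7_kon", "syt7_koff", "syt7_cooperativity",
                     "syt7_fusion_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.syt4_kon <= self.syt7_kon:
            raise ValueError("Syt4 must have the faster on-rate (syt4_kon > syt7_kon)")

    def replace(self, **kw) -> "SensorParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class VesiclePools:
    """Vesicle pool sizes and recycling rates.

    Released vesicles traverse endocytosis then reacidification on their
    own pathway (kiss-and-run or full-fusion) before rejoining the mobile
    pool; mobile vesicles dock at ``docking_rate`` while free docking
    sites remain.  Total vesicle number is conserved.
    """

    n_docked_init: int = _DEFAULTS["pools"]["n_docked_init"]
    n_mobile_init: int = _DEFAULTS["pools"]["n_mobile_init"]
    docked_capacity: int = _DEFAULTS["pools"]["docked_capacity"]
    kr_endo_rate: float = _DEFAULTS["pools"]["kr_endo_rate"]
    kr_reacid_rate: float = _DEFAULTS["pools"]["kr_reacid_rate"]
    ff_endo_rate: float = _DEFAULTS["pools"]["ff_endo_rate"]
    ff_reacid_rate: float = _DEFAULTS["pools"]["ff_reacid_rate"]
    docking_rate: float = _DEFAULTS["pools"]["docking_rate"]

    def validate(self) -> None:
        if self.n_docked_init < 0 or self.n_mobile_init < 0:
            raise ValueError("pool sizes must be non-negative integers")
        if self.docked_capacity < self.n_docked_init:
            raise ValueError("docked_capacity must be >= n_docked_init")
        for name in ("kr_endo_rate", "kr_reacid_rate", "ff_endo_rate",
                     "ff_reacid_rate", "docking_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def n_total(self) -> int:
        return self.n_docked_init + self.n_mobile_init

    def replace(self, **kw) -> "VesiclePools":
        return replace(self, **kw)


@dataclass(frozen=True)
class ConditionSpec:
    """Which amyloid-beta pathology transforms to apply."""

    abeta_mglur: bool = False
    abeta_pmca: bool = False

    @classmethod
    def from_name(cls, name: str) -> "ConditionSpec":
        table = {
            "control": cls(False, False),
            "mglur": cls(True, False),
            "pmca": cls(False, True),
            "both": cls(True, True),
        }
        try:
            return table[name]
        except KeyError:
            raise ValueError(
                f"unknown condition {name!r}; expected one of {sorted(table)}"
            ) from None

    @property
    def name(self) -> str:
        return {(False, False): "control", (True, False): "mglur",
                (False, True): "pmca", (True, True): "both"}[
            (self.abeta_mglur, self.abeta_pmca)]


def default_parameters() -> tuple[ModelParameters, SensorParameters, VesiclePools]:
    """Return the versioned default parameter set (validated)."""
    mp, sp, vp = ModelParameters(), SensorParameters(), VesiclePools()
    mp.validate()
    sp.validate()
    vp.validate()
    return mp, sp, vp


def load_parameters(path) -> tuple[ModelParameters, SensorParameters, VesiclePools]:
    """Load a parameter file (JSON with 'model'/'sensors'/'pools' blocks).

    Missing keys fall back to the bundled defaults.
    """
    with open(path) as fh:
        blob = json.load(fh)
    mp = ModelParameters(**{k: v for k, v in blob.get("model", {}).items()})
    sp = SensorParameters(**{k: v for k, v in blob.get("sensors", {}).items()})
    vp = VesiclePools(**{k: v for k, v in blob.get("pools", {}).items()})
    mp.validate(); sp.validate(); vp.validate()
    return mp, sp, vp


def save_parameters(path, mp: ModelParameters, sp: SensorParameters,
                    vp: VesiclePools) -> None:
    model = asdict(mp)
    model.pop("applied_conditions", None)
    blob = {"model": model, "sensors": asdict(sp), "pools": asdict(vp)}
    blob["sensors"].pop("n_syt7_sites", None)
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=2)
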