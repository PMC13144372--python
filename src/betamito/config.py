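"""Simulation configuration.

All rate constants, thresholds, packet sizes and initial counts of the
beta-cell model live in a single :class:`SimConfig`.  The five
health-coupling parameters (``f_ATP``, ``damage_lim``, ``damage_m``,
``asym_fission``, ``Thr_damage``) default to the fitted Fis1-knockdown
parameter set; the metabolic and signalling constants are repo-calibrated
stand-ins for the detailed published cascades (see ``docs/methods.md``).

Units: time is seconds throughout; volume is in arbitrary units with
``V_target`` the whole-cell mitochondrial volume; health/damage are integer
units at density ``u`` per volume unit; ATP and pyruvate are counted in
packets (a packet abstracts ``atp_packet_size`` molecules); Ca2+ is a
dimensionless concentration in [0, Ca_max].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class SimConfig:
    # --- health-coupling parameters (fitted set) ---
    f_ATP: float = 1.54            # oxPhos scaling factor, dimensionless
    damage_lim: float = 0.533      # health-fraction midpoint of the oxPhos sigmoid
    damage_m: float = 28.7         # sigmoid steepness, dimensionless
    asym_fission: float = 0.0922   # damage fraction shifted into the small daughter
    Thr_damage: float = 0.74       # damage fraction blocking fusion / enabling mitophagy

    # --- mitochondrial population ---
    n_mito_init: int = 68
    V_target: float = 68.0         # volume set-point of the whole network
    u: int = 400                   # health units per volume unit
    init_damage_frac: float = 0.30 # initial per-mitochondrion damage fraction

    # --- Drp1 / anchor sites ---
    drp1_clusters_init: int = 20000  # Drp1_10 clusters; 20000 = WT
    n_fis1: int = 306
    n_mff: int = 306
    ring_threshold: int = 27       # bound clusters required to arm a fission site
    ring_slack: int = 0            # site capacity = ring_threshold + ring_slack
    k_bind: float = 4e-5           # 1/s per (free cluster x open slot)
    k_unbind: float = 6e-4         # 1/s per bound cluster
    k_pka: float = 0.002           # 1/s, Drp1 phosphorylation (cAMP-activated PKA)
    K_pka_camp: float = 25.0
    k_can: float = 0.002           # 1/s, Drp1 dephosphorylation (Ca-activated CaN)
    K_can_ca: float = 0.3

    # --- fission / fusion / mitophagy / biogenesis ---
    k_fission: float = 0.0016      # 1/s per volume unit, per armed site
    mu_mid: float = 0.5
    sigma_mid: float = 0.05
    mu_peri: float = 0.09
    sigma_peri: float = 0.04
    k_fusion: float = 2.5e-4       # 1/s per unordered fusable pair
    k_mitophagy: float = 0.12      # 1/s per eligible mitochondrion
    v_phagy_max: float = 0.5       # autophagosome size cutoff (volume units)
    k_grow: float = 1.0            # 1/s per volume-unit deficit
    growth_quantum: float = 0.02   # volume added per biogenesis event

    # --- metabolism (packet units) ---
    glucose_mM: float = 25.0
    Vmax_glyc: float = 0.5         # glycolysis firings/s at glucose saturation
    Km_glyc: float = 8.0           # mM
    k_oxphos: float = 0.0175       # 1/s per (volume x modifier) unit
    Km_oxphos_pyr: float = 5.0     # pyruvate packets
    atp_per_pyr: float = 15        # ATP packets per pyruvate packet oxidized
    Vmax_LDH: float = 0.6          # fermentation firings/s at saturation
    Km_LDH_pyr: float = 150.0      # pyruvate packets
    k_ros: float = 9.6             # damage conversions per oxPhos firing rate
    k_repair: float = 2e-5         # 1/s per damage unit
    k_atp_use: float = 0.025       # 1/s per ATP packet
    atp_packet_size: float = 1e6   # molecules per ATP packet (bookkeeping only)
    pyr_packet_size: float = 1e6   # molecules per pyruvate packet (bookkeeping only)

    # --- cAMP ---
    k_ac: float = 0.5              # cAMP synthesis at ATP saturation, 1/s
    Km_ac_atp: float = 200.0       # ATP packets
    k_pde: float = 0.01            # 1/s per cAMP

    # --- calcium (continuous, relaxation toward ATP-dependent target) ---
    Ca_basal: float = 0.15
    Ca_max: float = 1.0
    K_Ca: float = 500.0            # ATP-packet half point
    n_Ca: float = 3.0
    tau_Ca: float = 30.0           # relaxation time constant, s

    # --- insulin secretion ---
    k_sec: float = 0.004           # 1/s per RRP granule at Ca saturation
    K_sec_ca: float = 0.55
    n_sec: float = 2.5
    k_refill: float = 0.01         # 1/s per free RRP slot at glucose saturation
    Km_refill_gluc: float = 8.0    # mM
    RRP_cap: int = 200
    rrp_init: int = 200

    # --- initial pools ---
    atp_init: int = 400
    pyr_init: int = 10
    camp_init: int = 30

    # --- run control ---
    seed: int = 0
    t_end: float = 3000.0
    record_interval: float = 10.0

    def __post_init__(self) -> None:
        self.validate()

    # fields that must lie in [0, 1]
    _FRACTIONS = (
        "damage_lim", "asym_fission", "Thr_damage", "init_damage_frac",
        "mu_mid", "mu_peri",
    )
    _POSITIVE = ("V_target", "u", "atp_packet_size", "pyr_packet_size",
                 "tau_Ca", "Ca_max", "K_Ca", "K_sec_ca", "growth_quantum")
    _COUNTS = ("n_mito_init", "drp1_clusters_init", "n_fis1", "n_mff",
               "RRP_cap", "rrp_init", "atp_init", "pyr_init", "camp_init")

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and (v != v):  # NaN
                raise ConfigError(f"{f.name}: must be finite")
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1], got {v}")
        for name in self._POSITIVE:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")
        for name in self._COUNTS:
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ConfigError(f"{name}: must be a non-negative integer")
        if self.ring_threshold < 1:
            raise ConfigError("ring_threshold: must be >= 1")
        if self.ring_slack < 0:
            raise ConfigError("ring_slack: must be >= 0")
        if self.n_mito_init < 1:
            raise ConfigError("n_mito_init: must be >= 1")
        for name in ("k_bind", "k_unbind", "k_pka", "k_can", "k_fission",
                     "k_fusion", "k_mitophagy", "k_grow", "Vmax_glyc",
                     "k_oxphos", "Vmax_LDH", "k_ros", "k_repair", "k_atp_use",
                     "k_ac", "k_pde", "k_sec", "k_refill", "atp_per_pyr",
                     "glucose_mM", "sigma_mid", "sigma_peri", "Ca_basal",
                     "Km_glyc", "Km_oxphos_pyr", "Km_LDH_pyr", "Km_ac_atp",
                     "Km_refill_gluc", "K_pka_camp", "K_can_ca", "n_Ca",
                     "n_sec", "v_phagy_max", "t_end", "record_interval"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.Ca_max < self.Ca_basal:
            raise ConfigError("Ca_max: must be >= Ca_basal")
        if self.rrp_init > self.RRP_cap:
            raise ConfigError("rrp_init: must be <= RRP_cap")

    @property
    def site_capacity(self) -> int:
        return self.ring_threshold + self.ring_slack

    def replace(self, **kwargs) -> "SimConfig":
        """Return a validated copy with the given fields overridden."""
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ConfigError(f"{sorted(unknown)[0]}: unknown configuration key")
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{sorted(unknown)[0]}: unknown configuration key")
        return cls(**data)
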