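"""Glucose -> pyruvate -> ATP fluxes, health-coupled oxPhos, ROS damage,
repair, ATP consumption and cAMP turnover.

The glycolysis/oxPhos cascade is condensed to lumped Michaelis-Menten
steps in packet units: a glycolysis firing converts one glucose equivalent
into 2 pyruvate packets + 2 ATP packets; an oxPhos firing oxidizes one
pyruvate packet into ``atp_per_pyr`` ATP packets, scaled per mitochondrion
by volume and by the health-dependent sigmoid modifier.  All kinetic
constants of this cascade are repo-calibrated stand-ins, not published
values (see docs/methods.md for the calibration criteria).
"""

from __future__ import annotations

import math

from .config import SimConfig


def oxphos_modifier(health: int, damage: int, config: SimConfig) -> float:
    """Multiplicative oxPhos modifier ``f`` of a mitochondrion.

    ``f = f_ATP * (0.1 + 0.9 / (1 + exp(damage_m * (damage_lim - h))))``
    with ``h = health/(health+damage)`` the health fraction.  ``f`` rises
    sigmoidally from ``0.1*f_ATP`` (fully damaged) to ``~f_ATP`` (fully
    healthy) with midpoint ``0.55*f_ATP`` at ``h = damage_lim``.
    """
    total = health + damage
    if total <= 0:
        raise ValueError("oxphos_modifier: health + damage must be > 0")
    h = health / total
    x = config.damage_m * (config.damage_lim - h)
    # guard exp overflow for extreme steepness
    if x > 700.0:
        sig = 0.0
    else:
        sig = 1.0 / (1.0 + math.exp(x))
    return config.f_ATP * (0.1 + 0.9 * sig)


def glycolysis_propensity(config: SimConfig) -> float:
    """Michaelis-Menten in extracellular glucose; saturates at Vmax_glyc."""
    g = config.glucose_mM
    return config.Vmax_glyc * g / (config.Km_glyc + g) if g > 0 else 0.0


def fermentation_propensity(pyr: int, config: SimConfig) -> float:
    """Anaerobic pyruvate removal (LDH), Michaelis-Menten in pyruvate."""
    return config.Vmax_LDH * pyr / (config.Km_LDH_pyr + pyr) if pyr > 0 else 0.0


def oxphos_propensity(w: float, pyr: int, config: SimConfig) -> float:
    """oxPhos rate for weight ``w`` = volume x modifier (single
    mitochondrion) or the network sum of those weights."""
    if pyr <= 0 or w <= 0.0:
        return 0.0
    return config.k_oxphos * w * pyr / (config.Km_oxphos_pyr + pyr)


def ros_damage_propensity(w_ros: float, pyr: int, config: SimConfig) -> float:
    """Health->damage conversion proportional to the oxPhos rate; only
    mitochondria with at least one health unit contribute to ``w_ros``."""
    return config.k_ros * oxphos_propensity(w_ros, pyr, config)


def repair_propensity(damage: int, config: SimConfig) -> float:
    """Damage->health back-conversion (protein/mtDNA turnover)."""
    return config.k_repair * damage


def atp_consumption_propensity(atp: int, config: SimConfig) -> float:
    return config.k_atp_use * atp


def camp_synthesis_propensity(atp: int, config: SimConfig) -> float:
    """Adenylate-cyclase ATP->cAMP conversion, saturating in ATP."""
    return config.k_ac * atp / (config.Km_ac_atp + atp) if atp > 0 else 0.0


def camp_degradation_propensity(camp: int, config: SimConfig) -> float:
    """Phosphodiesterase-mediated first-order cAMP decay."""
    return config.k_pde * camp
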