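"""Mitochondrial fission and fusion mechanics.

Peripheral fission sorts damage: the small daughter inherits its volume
share of the mother's damage plus an extra ``asym_fission`` fraction
(e.g. a 25/75 split with 5% asymmetry puts 25%+5% = 30% of the mother's
damage into the small daughter).  Midzone fission splits near the middle
with no sorting.  The daughters' health follows the ceil/floor complement
scheme, so volume, health and damage are conserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Tuple

import numpy as np

from .config import SimConfig
from .state import Mitochondrion

FissionType = Literal["midzone", "peripheral"]


def sample_fission_ratio(fission_type: FissionType, rng: np.random.Generator,
                         config: SimConfig) -> int:
    """Draw the fission position r2 (per-mille integer in [1, 999]).

    Midzone positions are normal around ``mu_mid``; peripheral positions
    are normal around ``mu_peri`` and folded so that r2 always denotes the
    SMALL side.  Draws outside (0, 1) are redrawn (truncation).
    """
    if fission_type == "midzone":
        mu, sigma = config.mu_mid, config.sigma_mid
    elif fission_type == "peripheral":
        mu, sigma = config.mu_peri, config.sigma_peri
    else:
        raise ValueError(f"unknown fission type {fission_type!r}")
    if sigma == 0.0:
        r = mu
    else:
        for _ in range(1000):
            r = mu + sigma * rng.standard_normal()
            if 0.0 < r < 1.0:
                break
        else:  # pathological sigma; fall back to the mean
            r = min(max(mu, 1e-3), 1 - 1e-3)
    if fission_type == "peripheral":
        r = min(r, 1.0 - r)
    r2 = int(round(1000.0 * r))
    return min(max(r2, 1), 999)


@dataclass
class FissionOutcome:
    small: Mitochondrion
    large: Mitochondrion
    type: FissionType
    r2: int
    released: int  # Drp1_10 clusters returned to the free pool


def split_health_damage(health: int, damage: int, r2: int,
                        asym: float) -> Tuple[int, int, int, int]:
    """Partition the mother's (health, damage) units at position r2/1000
    with damage asymmetry ``asym`` toward the small side.

    Returns (health_small, damage_small, health_large, damage_large);
    the four values are non-negative and sum component-wise to the
    mother's attributes.
    """
    if not 1 <= r2 <= 999:
        raise ValueError("r2 must be in [1, 999]")
    units = health + damage
    if units < 2:
        raise ValueError("cannot split a mitochondrion with < 2 units")
    r = r2 / 1000.0
    units_small = min(max(int(round(units * r)), 1), units - 1)
    hs = math.ceil(health * r - damage * asym)
    hs = max(0, min(hs, health, units_small))
    ds = units_small - hs
    if ds > damage:  # cap the shifted damage at what the mother carries
        ds = damage
        hs = units_small - ds
    return hs, ds, health - hs, damage - ds


def execute_fission(mito: Mitochondrion, site_kind: str, site_index: int,
                    r2: int, config: SimConfig, rng: np.random.Generator,
                    id_small: int, id_large: int) -> FissionOutcome:
    """Split ``mito`` at the armed site (``site_kind``, ``site_index``).

    The triggering ring disassembles (its clusters are released,
    unphosphorylated); every other anchor site moves to the small daughter
    independently with probability r = r2/1000, volume-proportional in
    expectation.  Damage sorting applies to peripheral events only.
    """
    sites = mito.fis1_sites if site_kind == "fis1" else mito.mff_sites
    if sites[site_index] < config.ring_threshold:
        raise ValueError("fission requires a complete Drp1 ring at the site")
    ftype: FissionType = "peripheral" if site_kind == "fis1" else "midzone"
    asym = config.asym_fission if ftype == "peripheral" else 0.0
    hs, ds, hl, dl = split_health_damage(mito.health, mito.damage, r2, asym)
    released = sites[site_index]
    sites[site_index] = 0
    r = r2 / 1000.0
    small = Mitochondrion(id=id_small, health=hs, damage=ds)
    large = Mitochondrion(id=id_large, health=hl, damage=dl)
    for kind in ("fis1", "mff"):
        for b in getattr(mito, f"{kind}_sites"):
            target = small if rng.random() < r else large
            getattr(target, f"{kind}_sites").append(b)
    return FissionOutcome(small=small, large=large, type=ftype, r2=r2,
                          released=released)


def fuse(m1: Mitochondrion, m2: Mitochondrion, new_id: int) -> Mitochondrion:
    """Merge two mitochondria: volumes, health, damage add; anchor-site
    lists concatenate; bound Drp1 stays bound."""
    return Mitochondrion(
        id=new_id,
        health=m1.health + m2.health,
        damage=m1.damage + m2.damage,
        fis1_sites=list(m1.fis1_sites) + list(m2.fis1_sites),
        mff_sites=list(m1.mff_sites) + list(m2.mff_sites),
    )


def fission_propensity(mito: Mitochondrion, bound: int,
                       config: SimConfig) -> float:
    """Rate of a single site: k_fission * volume if the ring is complete."""
    if bound >= config.ring_threshold and mito.units >= 2:
        return config.k_fission * mito.units / config.u
    return 0.0
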