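"""The integrated beta-cell model: rule set composition and `simulate`.

Builds the fixed, parameterized rule set (Drp1 cycling, fission/fusion,
mitophagy, biogenesis, metabolism, cAMP, secretion) over a
:class:`~betamito.state.CellState` and runs it with the Gillespie kernel.
Ca2+ is the one continuous variable: it relaxes toward its ATP-dependent
target between events.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from . import metabolism as met
from . import mito as mdyn
from . import signaling as sig
from .config import SimConfig
from .engine import Simulator, Trajectory
from .signaling import hill
from .state import CellState, Mitochondrion, initialize_state


def _pick_weighted(mitos: List[Mitochondrion], attr: str, total: float,
                   rng: np.random.Generator) -> Mitochondrion:
    x = rng.random() * total
    acc = 0.0
    last = None
    for m in mitos:
        w = getattr(m, attr)
        if w > 0:
            last = m
            acc += w
            if x < acc:
                return m
    if last is None:
        raise RuntimeError(f"no mitochondrion with positive {attr}")
    return last  # float round-off fallback


class _Rule:
    name = "abstract"

    def __init__(self, config: SimConfig):
        self.cfg = config

    def propensity(self, s: CellState) -> float:  # pragma: no cover
        raise NotImplementedError

    def execute(self, s: CellState, rng) -> Optional[dict]:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------- metabolism
class Glycolysis(_Rule):
    name = "glycolysis"

    def propensity(self, s):
        return met.glycolysis_propensity(self.cfg)

    def execute(self, s, rng):
        s.pyr += 2
        s.atp += 2
        return None


class Fermentation(_Rule):
    name = "fermentation"

    def propensity(self, s):
        return met.fermentation_propensity(s.pyr, self.cfg)

    def execute(self, s, rng):
        s.pyr -= 1
        return None


class OxPhos(_Rule):
    name = "oxphos"

    def __init__(self, config):
        super().__init__(config)
        self._atp_yield = int(round(config.atp_per_pyr))

    def propensity(self, s):
        return met.oxphos_propensity(s.W, s.pyr, self.cfg)

    def execute(self, s, rng):
        _pick_weighted(s.mitos, "w", s.W, rng)  # volume x modifier weighting
        s.pyr -= 1
        s.atp += self._atp_yield
        return None


class RosDamage(_Rule):
    name = "ros_damage"

    def propensity(self, s):
        return met.ros_damage_propensity(s.W_ros, s.pyr, self.cfg)

    def execute(self, s, rng):
        m = _pick_weighted(s.mitos, "w_ros", s.W_ros, rng)
        m.health -= 1
        m.damage += 1
        s.refresh_mito(m)
        return {"mito": m.id}


class Repair(_Rule):
    name = "repair"

    def propensity(self, s):
        return met.repair_propensity(s.D_tot, self.cfg)

    def execute(self, s, rng):
        m = _pick_weighted(s.mitos, "damage", float(s.D_tot), rng)
        m.damage -= 1
        m.health += 1
        s.refresh_mito(m)
        return {"mito": m.id}


class AtpConsumption(_Rule):
    name = "atp_use"

    def propensity(self, s):
        return met.atp_consumption_propensity(s.atp, self.cfg)

    def execute(self, s, rng):
        s.atp -= 1
        return None


class CampSynthesis(_Rule):
    name = "camp_synth"

    def propensity(self, s):
        return met.camp_synthesis_propensity(s.atp, self.cfg)

    def execute(self, s, rng):
        s.camp += 1
        return None


class CampDegradation(_Rule):
    name = "camp_deg"

    def propensity(self, s):
        return met.camp_degradation_propensity(s.camp, self.cfg)

    def execute(self, s, rng):
        s.camp -= 1
        return None


# ---------------------------------------------------------------- Drp1 cycle
class Drp1Bind(_Rule):
    """Free unphosphorylated Drp1_10 binds a random open anchor slot."""
    name = "drp1_bind"

    def propensity(self, s):
        return self.cfg.k_bind * s.drp1_free_u * s.open_slots_total

    def execute(self, s, rng):
        m = _pick_weighted(s.mitos, "open_slots", float(s.open_slots_total), rng)
        cap = self.cfg.site_capacity
        x = rng.random() * m.open_slots
        acc = 0.0
        for sites in (m.fis1_sites, m.mff_sites):
            for i, b in enumerate(sites):
                acc += cap - b
                if x < acc:
                    sites[i] += 1
                    s.drp1_free_u -= 1
                    s.refresh_mito(m)
                    return None
        # round-off fallback: first non-full slot
        for sites in (m.fis1_sites, m.mff_sites):
            for i, b in enumerate(sites):
                if b < cap:
                    sites[i] += 1
                    s.drp1_free_u -= 1
                    s.refresh_mito(m)
                    return None
        return None


class Drp1Unbind(_Rule):
    name = "drp1_unbind"

    def propensity(self, s):
        return self.cfg.k_unbind * s.bound_total

    def execute(self, s, rng):
        m = _pick_weighted(s.mitos, "bound", float(s.bound_total), rng)
        x = rng.random() * m.bound
        acc = 0.0
        for sites in (m.fis1_sites, m.mff_sites):
            for i, b in enumerate(sites):
                acc += b
                if x < acc and b > 0:
                    sites[i] -= 1
                    s.drp1_free_u += 1
                    s.refresh_mito(m)
                    return None
        for sites in (m.fis1_sites, m.mff_sites):
            for i, b in enumerate(sites):
                if b > 0:
                    sites[i] -= 1
                    s.drp1_free_u += 1
                    s.refresh_mito(m)
                    return None
        return None


class Drp1Phosphorylate(_Rule):
    """PKA (cAMP-activated) phosphorylates free Drp1, blocking binding."""
    name = "drp1_phos"

    def propensity(self, s):
        return self.cfg.k_pka * hill(s.camp, self.cfg.K_pka_camp) * s.drp1_free_u

    def execute(self, s, rng):
        s.drp1_free_u -= 1
        s.drp1_free_p += 1
        return None


class Drp1Dephosphorylate(_Rule):
    """Calcineurin (Ca2+-activated) dephosphorylates free Drp1."""
    name = "drp1_dephos"

    def propensity(self, s):
        return self.cfg.k_can * hill(s.ca, self.cfg.K_can_ca) * s.drp1_free_p

    def execute(self, s, rng):
        s.drp1_free_p -= 1
        s.drp1_free_u += 1
        return None


# ------------------------------------------------- fission / fusion / QC
class Fission(_Rule):
    """Fission at an armed site; Fis1 -> peripheral, MFF -> midzone."""

    def __init__(self, config: SimConfig, kind: str):
        super().__init__(config)
        self.kind = kind  # "fis1" | "mff"
        self.name = ("fission_peripheral" if kind == "fis1"
                     else "fission_midzone")
        self.ftype = "peripheral" if kind == "fis1" else "midzone"
        self._attr = "armed_f" if kind == "fis1" else "armed_m"

    def propensity(self, s):
        total = s.armed_v_fis1 if self.kind == "fis1" else s.armed_v_mff
        return self.cfg.k_fission * max(0.0, total)  # clamp float drift

    def execute(self, s, rng):
        total = s.armed_v_fis1 if self.kind == "fis1" else s.armed_v_mff
        m = _pick_weighted(s.mitos, self._attr, total, rng)
        sites = m.fis1_sites if self.kind == "fis1" else m.mff_sites
        armed = [i for i, b in enumerate(sites)
                 if b >= self.cfg.ring_threshold]
        idx = armed[rng.integers(len(armed))]
        r2 = mdyn.sample_fission_ratio(self.ftype, rng, self.cfg)
        m.r2 = r2
        out = mdyn.execute_fission(m, self.kind, idx, r2, self.cfg, rng,
                                   id_small=s.new_id(), id_large=s.new_id())
        s.remove_mito(m)
        s.add_mito(out.small)
        s.add_mito(out.large)
        s.drp1_free_u += out.released  # ring disassembles, unphosphorylated
        return {"type": out.type, "r2": r2, "mother": m.id,
                "small": out.small.id, "large": out.large.id,
                "released": out.released}


class Fusion(_Rule):
    """Pairwise merge of two mitochondria below the damage threshold."""
    name = "fusion"

    def propensity(self, s):
        n = s.n_fusable
        return self.cfg.k_fusion * n * (n - 1) / 2.0

    def execute(self, s, rng):
        cand = s.fusable_mitos()
        i, j = rng.choice(len(cand), size=2, replace=False)
        m1, m2 = cand[int(i)], cand[int(j)]
        merged = mdyn.fuse(m1, m2, s.new_id())
        s.remove_mito(m1)
        s.remove_mito(m2)
        s.add_mito(merged)
        return {"a": m1.id, "b": m2.id, "merged": merged.id}


class Mitophagy(_Rule):
    """Removal of small mitochondria at/above the damage threshold.

    The removed mitochondrion's bound Drp1 returns to the free pool and
    its anchor sites relocate to a surviving mitochondrion, keeping the
    Fis1/MFF totals constant.  Disabled for the last mitochondrion.
    """
    name = "mitophagy"

    def propensity(self, s):
        if len(s.mitos) < 2:
            return 0.0
        return self.cfg.k_mitophagy * s.n_phagy_eligible

    def execute(self, s, rng):
        cand = s.phagy_eligible_mitos()
        m = cand[rng.integers(len(cand))]
        s.drp1_free_u += m.bound
        fis1 = len(m.fis1_sites)
        mff = len(m.mff_sites)
        s.remove_mito(m)
        host = s.mitos[rng.integers(len(s.mitos))]
        host.fis1_sites.extend([0] * fis1)
        host.mff_sites.extend([0] * mff)
        s.refresh_mito(host)
        return {"mito": m.id, "v": m.units / self.cfg.u,
                "damage_fraction": m.damage_fraction,
                "sites_rehomed": fis1 + mff, "host": host.id}


class Biogenesis(_Rule):
    """Growth restoring total mitochondrial volume toward V_target.

    The growing mitochondrion is chosen mass-proportionally, so biogenesis
    dilutes damage uniformly across the network instead of concentrating
    fresh health in small mitochondria.
    """
    name = "biogenesis"

    def __init__(self, config):
        super().__init__(config)
        self._quantum_units = max(1, round(config.u * config.growth_quantum))

    def propensity(self, s):
        return self.cfg.k_grow * max(0.0, self.cfg.V_target - s.total_volume)

    def execute(self, s, rng):
        m = _pick_weighted(s.mitos, "v_cached", s.total_volume, rng)
        m.health += self._quantum_units
        s.refresh_mito(m)
        return {"mito": m.id}


# ---------------------------------------------------------------- secretion
class InsulinRelease(_Rule):
    name = "insulin_release"

    def propensity(self, s):
        return sig.insulin_release_propensity(s.rrp, s.ca, self.cfg)

    def execute(self, s, rng):
        s.rrp -= 1
        s.secreted += 1
        return None


class RRPRefill(_Rule):
    name = "rrp_refill"

    def propensity(self, s):
        return sig.rrp_refill_propensity(s.rrp, self.cfg)

    def execute(self, s, rng):
        s.rrp += 1
        return None


def build_rules(config: SimConfig) -> List[_Rule]:
    return [
        Glycolysis(config), Fermentation(config), OxPhos(config),
        RosDamage(config), Repair(config), AtpConsumption(config),
        CampSynthesis(config), CampDegradation(config),
        Drp1Bind(config), Drp1Unbind(config),
        Drp1Phosphorylate(config), Drp1Dephosphorylate(config),
        Fission(config, "fis1"), Fission(config, "mff"),
        Fusion(config), Mitophagy(config), Biogenesis(config),
        InsulinRelease(config), RRPRefill(config),
    ]


def _snapshot(s: CellState) -> dict:
    return {
        "pyr": s.pyr, "atp": s.atp, "ca": s.ca, "camp": s.camp,
        "drp1_free_u": s.drp1_free_u, "drp1_free_p": s.drp1_free_p,
        "drp1_bound": s.bound_total, "rrp": s.rrp, "secreted": s.secreted,
        "n_mitos": len(s.mitos), "total_volume": s.total_volume,
        "damage_fraction": s.network_damage_fraction(),
        "mito_health": np.array([m.health for m in s.mitos]),
        "mito_damage": np.array([m.damage for m in s.mitos]),
        "mito_id": np.array([m.id for m in s.mitos]),
        "mito_bound_fis1": np.array([sum(m.fis1_sites) for m in s.mitos]),
        "mito_bound_mff": np.array([sum(m.mff_sites) for m in s.mitos]),
    }


def _make_hook(config: SimConfig):
    counter = {"n": 0}

    def hook(s: CellState, dt: float) -> None:
        s.ca = sig.relax_calcium(s.ca, s.atp, dt, config)
        counter["n"] += 1
        if counter["n"] >= 2000:  # wash out float drift in running sums
            counter["n"] = 0
            s.rebuild_aggregates()

    return hook


def make_simulator(config: SimConfig, seed: Optional[int] = None
                   ) -> Simulator:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    state = initialize_state(config, rng)
    return Simulator(build_rules(config), state, rng,
                     on_time_advance=_make_hook(config))


def simulate(config: SimConfig, seed: Optional[int] = None,
             record_events: bool = False,
             t_end: Optional[float] = None) -> Trajectory:
    """Run one trajectory; deterministic given (config, seed)."""
    if t_end is None:
        t_end = config.t_end
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    sim = make_simulator(config, seed)
    traj = sim.run(t_end, config.record_interval, _snapshot,
                   record_events=record_events)
    traj.seed = config.seed if seed is None else seed
    traj.config = config
    return traj
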