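"""Cell state: attributed mitochondrial compartments plus cytosolic pools.

A mitochondrion carries integer ``health`` and ``damage`` units at density
``u`` units per volume unit; its volume is exactly ``(health+damage)/u``,
so unit accounting is exact under fission, fusion, growth and removal.
Anchor sites (Fis1 -> peripheral fission, MFF -> midzone fission) are
represented by their bound Drp1_10 cluster counts.

The state maintains running aggregates (total oxPhos weight, armed-site
weight per fission type, open Drp1 slots, ...) so every rule propensity is
O(1); rules that pick a specific mitochondrion or site do a linear scan
only when they fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .config import SimConfig
from .metabolism import oxphos_modifier


@dataclass
class Mitochondrion:
    id: int
    health: int
    damage: int
    fis1_sites: List[int] = field(default_factory=list)  # bound Drp1 per site
    mff_sites: List[int] = field(default_factory=list)
    r2: Optional[int] = None  # pending fission position, per-mille

    # cached aggregate contributions (maintained by CellState; must only be
    # read/written through _compute_contrib/_add_contrib so that adding and
    # subtracting a mitochondrion's contribution always uses the same values)
    w: float = 0.0          # v * oxphos modifier
    w_ros: float = 0.0      # w if health >= 1 else 0
    armed_f: float = 0.0    # v * (# armed Fis1 sites)
    armed_m: float = 0.0    # v * (# armed MFF sites)
    open_slots: int = 0
    bound: int = 0
    v_cached: float = 0.0
    damage_cached: int = 0
    cls_fusable: bool = False
    cls_eligible: bool = False

    @property
    def units(self) -> int:
        return self.health + self.damage

    @property
    def damage_fraction(self) -> float:
        return self.damage / self.units

    def volume(self, u: int) -> float:
        return self.units / u


class CellState:
    """Mitochondria collection, cytosolic pools and the simulation clock."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.t = 0.0
        self.mitos: List[Mitochondrion] = []
        self._next_id = 0
        # pools
        self.pyr = 0
        self.atp = 0
        self.ca = config.Ca_basal
        self.camp = 0
        self.drp1_free_u = 0
        self.drp1_free_p = 0
        self.rrp = 0
        self.secreted = 0
        # aggregates
        self.W = 0.0
        self.W_ros = 0.0
        self.D_tot = 0
        self.total_volume = 0.0
        self.n_fusable = 0
        self.n_phagy_eligible = 0
        self.armed_v_fis1 = 0.0
        self.armed_v_mff = 0.0
        self.open_slots_total = 0
        self.bound_total = 0
        self._events_since_rebuild = 0

    # -- id management -------------------------------------------------
    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    # -- aggregate maintenance ----------------------------------------
    def _compute_contrib(self, m: Mitochondrion) -> None:
        cfg = self.config
        v = m.units / cfg.u
        f = oxphos_modifier(m.health, m.damage, cfg)
        m.w = v * f
        m.w_ros = m.w if m.health >= 1 else 0.0
        thr = cfg.ring_threshold
        cap = cfg.site_capacity
        if m.units >= 2:  # a 1-unit mitochondrion cannot split further
            m.armed_f = v * sum(1 for b in m.fis1_sites if b >= thr)
            m.armed_m = v * sum(1 for b in m.mff_sites if b >= thr)
        else:
            m.armed_f = m.armed_m = 0.0
        m.open_slots = (sum(cap - b for b in m.fis1_sites)
                        + sum(cap - b for b in m.mff_sites))
        m.bound = sum(m.fis1_sites) + sum(m.mff_sites)
        m.v_cached = v
        m.damage_cached = m.damage
        m.cls_fusable = m.damage_fraction < cfg.Thr_damage
        m.cls_eligible = (not m.cls_fusable) and v <= cfg.v_phagy_max

    def _add_contrib(self, m: Mitochondrion, sign: int) -> None:
        self.W += sign * m.w
        self.W_ros += sign * m.w_ros
        self.D_tot += sign * m.damage_cached
        self.total_volume += sign * m.v_cached
        self.armed_v_fis1 += sign * m.armed_f
        self.armed_v_mff += sign * m.armed_m
        self.open_slots_total += sign * m.open_slots
        self.bound_total += sign * m.bound
        if m.cls_fusable:
            self.n_fusable += sign
        elif m.cls_eligible:
            self.n_phagy_eligible += sign

    def add_mito(self, m: Mitochondrion) -> None:
        self._compute_contrib(m)
        self.mitos.append(m)
        self._add_contrib(m, +1)

    def remove_mito(self, m: Mitochondrion) -> None:
        self._add_contrib(m, -1)
        self.mitos.remove(m)

    def refresh_mito(self, m: Mitochondrion) -> None:
        """Re-derive a mitochondrion's cached contributions after mutation."""
        self._add_contrib(m, -1)
        self._compute_contrib(m)
        self._add_contrib(m, +1)

    def rebuild_aggregates(self) -> None:
        """Full recomputation; called periodically to wash out float drift."""
        self.W = self.W_ros = 0.0
        self.D_tot = 0
        self.total_volume = 0.0
        self.n_fusable = self.n_phagy_eligible = 0
        self.armed_v_fis1 = self.armed_v_mff = 0.0
        self.open_slots_total = self.bound_total = 0
        for m in self.mitos:
            self._compute_contrib(m)
            self._add_contrib(m, +1)

    # -- derived quantities -------------------------------------------
    @property
    def drp1_total(self) -> int:
        return self.drp1_free_u + self.drp1_free_p + self.bound_total

    def network_damage_fraction(self) -> float:
        units = sum(m.units for m in self.mitos)
        return self.D_tot / units if units else float("nan")

    def fusable_mitos(self) -> List[Mitochondrion]:
        thr = self.config.Thr_damage
        return [m for m in self.mitos if m.damage_fraction < thr]

    def phagy_eligible_mitos(self) -> List[Mitochondrion]:
        cfg = self.config
        return [m for m in self.mitos
                if m.damage_fraction >= cfg.Thr_damage
                and m.units / cfg.u <= cfg.v_phagy_max]

    def check_invariants(self, drp1_expected: Optional[int] = None) -> None:
        """Raise AssertionError if a structural invariant is violated."""
        for m in self.mitos:
            assert m.health >= 0 and m.damage >= 0, "negative attribute"
            assert m.units >= 1, "empty mitochondrion"
            cap = self.config.site_capacity
            assert all(0 <= b <= cap for b in m.fis1_sites + m.mff_sites), \
                "site bound count out of range"
        for name in ("pyr", "atp", "camp", "drp1_free_u", "drp1_free_p",
                     "rrp", "secreted"):
            assert getattr(self, name) >= 0, f"negative pool {name}"
        if drp1_expected is not None:
            assert self.drp1_total == drp1_expected, "Drp1 not conserved"


def initialize_state(config: SimConfig,
                     rng) -> CellState:
    """Build the initial cell: mitochondria summing to ``V_target`` volume,
    anchor sites spread volume-proportionally, all Drp1 free and
    unphosphorylated, pools at configured basal values."""
    config.validate()
    state = CellState(config)
    n = config.n_mito_init
    total_units = round(config.u * config.V_target)
    base = total_units // n
    rem = total_units - base * n
    units = [base + (1 if i < rem else 0) for i in range(n)]
    # anchor sites distributed proportionally to volume
    probs = [ui / total_units for ui in units]
    fis1_alloc = rng.multinomial(config.n_fis1, probs)
    mff_alloc = rng.multinomial(config.n_mff, probs)
    for i in range(n):
        dmg = round(config.init_damage_frac * units[i])
        m = Mitochondrion(
            id=state.new_id(),
            health=units[i] - dmg,
            damage=dmg,
            fis1_sites=[0] * int(fis1_alloc[i]),
            mff_sites=[0] * int(mff_alloc[i]),
        )
        state.add_mito(m)
    state.drp1_free_u = config.drp1_clusters_init
    state.drp1_free_p = 0
    state.pyr = config.pyr_init
    state.atp = config.atp_init
    state.camp = config.camp_init
    state.rrp = config.rrp_init
    from .signaling import calcium_target
    state.ca = calcium_target(state.atp, config)
    return state
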