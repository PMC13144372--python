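"""Damage-sorting fission, fusion, mitophagy and the Drp1 cycle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from betamito import SimConfig, initialize_state, split_health_damage
from betamito.cell import (Biogenesis, Drp1Bind, Drp1Phosphorylate, Fission,
                           Fusion, Mitophagy, build_rules)
from betamito.mito import (execute_fission, fission_propensity, fuse,
                           sample_fission_ratio)
from betamito.state import Mitochondrion


def make_mito(health, damage, fis1=(), mff=(), mid=0):
    return Mitochondrion(id=mid, health=health, damage=damage,
                         fis1_sites=list(fis1), mff_sites=list(mff))


class TestDamageSorting:
    def test_quarter_split_with_five_percent_asymmetry(self):
        """A 25/75 peripheral split at 5% asymmetry puts 25%+5% = 30% of
        the mother's damage into the small daughter."""
        hs, ds, hl, dl = split_health_damage(80, 20, r2=250, asym=0.05)
        assert ds / 20 == pytest.approx(0.30)          # 6 of 20 units
        assert hs == math.ceil(80 * 0.25 - 20 * 0.05)  # = 19
        assert hs + ds == 25                            # 25% of 100 units
        assert hl + dl == 75

    def test_symmetric_split_no_sorting(self):
        hs, ds, hl, dl = split_health_damage(100, 10, r2=500, asym=0.0)
        assert (hs, ds) == (50, 5) and (hl, dl) == (50, 5)

    def test_health_clamped_when_shift_exceeds_share(self):
        # tiny health share vs large damage shift: health_small floors at 0
        hs, ds, hl, dl = split_health_damage(5, 95, r2=20, asym=0.5)
        assert hs >= 0 and ds >= 0 and hl >= 0 and dl >= 0
        assert hs + hl == 5 and ds + dl == 95

    @given(health=st.integers(0, 2000), damage=st.integers(0, 2000),
           r2=st.integers(1, 999),
           asym=st.floats(0, 0.2, allow_nan=False))
    def test_conservation_exact(self, health, damage, r2, asym):
        """Fission conserves health and damage exactly, all parts >= 0."""
        if health + damage < 2:
            return
        hs, ds, hl, dl = split_health_damage(health, damage, r2, asym)
        assert hs + hl == health
        assert ds + dl == damage
        assert min(hs, ds, hl, dl) >= 0
        assert hs + ds >= 1 and hl + dl >= 1


class TestFissionRatio:
    def test_degenerate_normals(self):
        cfg = SimConfig(sigma_mid=0.0, mu_peri=0.25, sigma_peri=0.0)
        rng = np.random.default_rng(0)
        assert sample_fission_ratio("midzone", rng, cfg) == 500
        assert sample_fission_ratio("peripheral", rng, cfg) == 250

    def test_midzone_sample_mean(self):
        cfg = SimConfig()
        rng = np.random.default_rng(1)
        draws = [sample_fission_ratio("midzone", rng, cfg)
                 for _ in range(20000)]
        assert np.mean(draws) == pytest.approx(500, abs=3)
        assert all(1 <= r <= 999 for r in draws)

    def test_peripheral_denotes_small_side(self):
        cfg = SimConfig(mu_peri=0.8, sigma_peri=0.1)  # folded to small side
        rng = np.random.default_rng(2)
        assert all(sample_fission_ratio("peripheral", rng, cfg) <= 500
                   for _ in range(200))


class TestFissionPropensity:
    def test_guard_and_linearity(self):
        cfg = SimConfig(k_fission=0.001, ring_threshold=4, ring_slack=0,
                        u=100)
        m = make_mito(150, 50)  # units 200 -> v = 2.0
        assert fission_propensity(m, cfg.ring_threshold - 1, cfg) == 0.0
        rate = fission_propensity(m, cfg.ring_threshold, cfg)
        assert rate == pytest.approx(0.002)
        m2 = make_mito(300, 100)  # doubled volume
        assert fission_propensity(m2, cfg.ring_threshold, cfg) == \
            pytest.approx(2 * rate)


class TestExecuteFission:
    def test_ring_disassembles_and_sites_conserved(self):
        cfg = SimConfig(ring_threshold=4, ring_slack=0)
        m = make_mito(300, 100, fis1=[4, 2, 0], mff=[1, 3])
        rng = np.random.default_rng(3)
        out = execute_fission(m, "fis1", 0, r2=250, config=cfg, rng=rng,
                              id_small=10, id_large=11)
        assert out.released == 4
        assert out.type == "peripheral"
        n_sites = (len(out.small.fis1_sites) + len(out.large.fis1_sites),
                   len(out.small.mff_sites) + len(out.large.mff_sites))
        assert n_sites == (3, 2)
        bound = (sum(out.small.fis1_sites) + sum(out.large.fis1_sites)
                 + sum(out.small.mff_sites) + sum(out.large.mff_sites))
        assert bound == 2 + 0 + 1 + 3  # everything except the fired ring
        assert out.small.units + out.large.units == 400

    def test_incomplete_ring_rejected(self):
        cfg = SimConfig(ring_threshold=4, ring_slack=0)
        m = make_mito(300, 100, fis1=[3])
        with pytest.raises(ValueError):
            execute_fission(m, "fis1", 0, 250, cfg,
                            np.random.default_rng(0), 1, 2)


class TestFusion:
    def test_fusion_merges_attributes(self):
        a = make_mito(70, 30, fis1=[2], mff=[1], mid=0)
        b = make_mito(50, 50, fis1=[0], mff=[4], mid=1)
        m = fuse(a, b, new_id=2)
        assert (m.health, m.damage) == (120, 80)
        assert m.fis1_sites == [2, 0] and m.mff_sites == [1, 4]

    def test_fission_then_fusion_recovers_mother(self):
        """Midzone fission at r2=500 with no sorting, then refusion,
        recovers the mother's totals exactly."""
        cfg = SimConfig(ring_threshold=4, ring_slack=0, asym_fission=0.0)
        m = make_mito(160, 40, mff=[4])
        rng = np.random.default_rng(4)
        out = execute_fission(m, "mff", 0, 500, cfg, rng, 1, 2)
        back = fuse(out.small, out.large, 3)
        assert (back.health, back.damage) == (160, 40)

    def test_fusable_excludes_at_threshold(self, rng):
        """A mitochondrion exactly at the damage threshold cannot fuse."""
        cfg = SimConfig(Thr_damage=0.5, n_mito_init=2, n_fis1=0, n_mff=0,
                        init_damage_frac=0.0)
        state = initialize_state(cfg, rng)
        m = state.mitos[0]
        m.damage = m.health = m.units // 2
        state.refresh_mito(m)
        assert state.n_fusable == 1
        assert m not in state.fusable_mitos()
        rule = Fusion(cfg)
        assert rule.propensity(state) == 0.0  # no fusable pair left

    def test_pair_count_propensity(self, rng):
        cfg = SimConfig(n_mito_init=2, init_damage_frac=0.0)
        state = initialize_state(cfg, rng)
        assert Fusion(cfg).propensity(state) == pytest.approx(cfg.k_fusion)


class TestMitophagy:
    def _state(self, rng, **kw):
        cfg = SimConfig(n_mito_init=4, init_damage_frac=0.0, **kw)
        return cfg, initialize_state(cfg, rng)

    def test_large_healthy_not_eligible(self, rng):
        cfg, state = self._state(rng)
        assert Mitophagy(cfg).propensity(state) == 0.0

    def test_small_fully_damaged_eligible(self, rng):
        cfg, state = self._state(rng, v_phagy_max=20.0)
        m = state.mitos[0]
        m.damage, m.health = m.units, 0
        state.refresh_mito(m)
        assert Mitophagy(cfg).propensity(state) == \
            pytest.approx(cfg.k_mitophagy)

    def test_removal_conserves_drp1_and_sites(self, rng):
        cfg, state = self._state(rng, v_phagy_max=20.0)
        m = state.mitos[1]
        m.damage, m.health = m.units, 0
        m.fis1_sites[0] = 3
        state.refresh_mito(m)
        sites_before = sum(len(x.fis1_sites) + len(x.mff_sites)
                           for x in state.mitos)
        drp1_before = state.drp1_total
        Mitophagy(cfg).execute(state, rng)
        assert len(state.mitos) == 3
        assert state.drp1_total == drp1_before
        assert sum(len(x.fis1_sites) + len(x.mff_sites)
                   for x in state.mitos) == sites_before


class TestBiogenesis:
    def test_setpoint_and_deficit(self, rng):
        cfg = SimConfig(n_mito_init=4, k_grow=0.1)
        state = initialize_state(cfg, rng)
        assert Biogenesis(cfg).propensity(state) == pytest.approx(0.0)
        m = state.mitos[0]
        m.health -= cfg.u  # remove one volume unit of health
        state.refresh_mito(m)
        assert Biogenesis(cfg).propensity(state) == pytest.approx(0.1)


class TestDrp1Cycle:
    def test_empty_pool_rates_zero(self, rng):
        cfg = SimConfig(drp1_clusters_init=0)
        state = initialize_state(cfg, rng)
        assert Drp1Bind(cfg).propensity(state) == 0.0
        assert Drp1Phosphorylate(cfg).propensity(state) == 0.0

    def test_phosphorylation_half_saturation(self, rng):
        cfg = SimConfig()
        state = initialize_state(cfg, rng)
        state.camp = int(cfg.K_pka_camp)
        expect = 0.5 * cfg.k_pka * state.drp1_free_u
        assert Drp1Phosphorylate(cfg).propensity(state) == \
            pytest.approx(expect)

    def test_phospho_cycle_two_state_equilibrium(self, rng):
        """Isolated (de)phosphorylation is a two-state chain: the
        stationary unphosphorylated fraction is d/(p+d)."""
        from betamito.cell import Drp1Dephosphorylate
        from betamito.engine import Simulator
        cfg = SimConfig(camp_init=60, drp1_clusters_init=2000, n_fis1=0,
                        n_mff=0)
        state = initialize_state(cfg, rng)
        state.ca = 0.4
        rules = [Drp1Phosphorylate(cfg), Drp1Dephosphorylate(cfg)]
        p = rules[0].propensity(state) / state.drp1_free_u
        sim = Simulator(rules, state, rng)
        traj = sim.run(20000.0, 50.0, lambda s: s.drp1_free_u)
        d = cfg.k_can * (state.ca / (cfg.K_can_ca + state.ca))
        expect = d / (p + d)
        observed = np.mean(traj.snapshots[100:]) / cfg.drp1_clusters_init
        assert observed == pytest.approx(expect, abs=0.03)


def test_initialization_counts(rng):
    cfg = SimConfig(n_mito_init=68, drp1_clusters_init=20000)
    state = initialize_state(cfg, rng)
    assert len(state.mitos) == 68
    assert state.drp1_free_u == 20000 and state.drp1_free_p == 0
    assert sum(len(m.fis1_sites) for m in state.mitos) == cfg.n_fis1
    assert sum(len(m.mff_sites) for m in state.mitos) == cfg.n_mff


def test_initialization_unit_density(rng):
    cfg = SimConfig(u=100, V_target=68.0)
    state = initialize_state(cfg, rng)
    assert sum(m.units for m in state.mitos) == 6800


def test_degenerate_single_mito_no_sites(rng):
    cfg = SimConfig(n_mito_init=1, n_fis1=0, n_mff=0)
    state = initialize_state(cfg, rng)
    assert len(state.mitos) == 1
    assert state.mitos[0].fis1_sites == [] and state.mitos[0].mff_sites == []
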