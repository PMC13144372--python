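"""Batch runners and statistics: factorial damage scans, knockdown scans,
glucose dose-response, Sobol sensitivity of insulin secretion, and a
particle-swarm fitting hook.

All runners are deterministic given ``base_seed``; replicate ``r`` of a
batch uses seed ``base_seed + r``.  Steady-state statistics use a fixed
simulated horizon with a burn-in fraction (default 0.5); fission,
mitophagy and secretion rates come from event counts over the
post-burn-in window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cell import simulate
from .config import SimConfig
from .engine import Trajectory
from .optimize import PSOResult, particle_swarm
from .sensitivity import SobolResult, sobol_indices

# parameter order and Table-derived bounds for the sensitivity analysis
SENSITIVITY_PARAMS = ["f_ATP", "damage_lim", "damage_m", "asym_fission",
                      "Thr_damage"]
SENSITIVITY_BOUNDS = {
    "f_ATP": (0.9, 1.6),
    "damage_lim": (0.25, 0.75),
    "damage_m": (10.0, 50.0),
    "asym_fission": (0.0, 0.10),
    "Thr_damage": (0.10, 0.90),
}


@dataclass
class SummaryStats:
    """Steady-state observables of one or more replicate trajectories."""
    mean_damage_pct: float
    damage_fractions: np.ndarray       # pooled per-mitochondrion, in [0, 1]
    volumes: np.ndarray                # pooled per-mitochondrion volumes
    peripheral_fission_rate: float     # events / s
    midzone_fission_rate: float
    mitophagy_rate: float
    mean_n_mitos: float
    secretion_rate: float              # granules / s
    n_replicates: int
    window: tuple

    def damage_percentile(self, q: float) -> float:
        return float(np.percentile(self.damage_fractions, q) * 100.0)


def _window_counts(traj: Trajectory, i0: int, name: str) -> float:
    start = traj.count_history[i0].get(name, 0)
    end = traj.event_counts.get(name, 0)
    return end - start


def steady_state_summary(trajectories: Sequence[Trajectory],
                         burn_in_fraction: float = 0.5) -> SummaryStats:
    """Average steady-state statistics over replicate trajectories.

    Snapshots with t >= burn_in_fraction * t_final enter the damage and
    volume statistics; event rates are window counts / elapsed time.
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    if not trajectories:
        raise ValueError("no trajectories given")
    dmg_net, dmg_pool, vol_pool, nm = [], [], [], []
    peri, mid, phagy, secr, elapsed = 0.0, 0.0, 0.0, 0.0, 0.0
    u = trajectories[0].config.u
    for traj in trajectories:
        times = np.asarray(traj.snapshot_times)
        t_burn = burn_in_fraction * traj.t_final
        idx = np.nonzero(times >= t_burn - 1e-9)[0]
        if len(idx) == 0:
            raise ValueError("no snapshots after burn-in")
        i0 = int(idx[0])
        for i in idx:
            snap = traj.snapshots[i]
            dmg_net.append(snap["damage_fraction"])
            units = snap["mito_health"] + snap["mito_damage"]
            dmg_pool.append(snap["mito_damage"] / units)
            vol_pool.append(units / u)
            nm.append(snap["n_mitos"])
        dt = traj.t_final - times[i0]
        if dt > 0:
            peri += _window_counts(traj, i0, "fission_peripheral")
            mid += _window_counts(traj, i0, "fission_midzone")
            phagy += _window_counts(traj, i0, "mitophagy")
            s0 = traj.snapshots[i0]["secreted"]
            secr += traj.snapshots[-1]["secreted"] - s0
            elapsed += dt
    if elapsed <= 0:
        elapsed = float("inf")  # single-snapshot window: rates are zero
    return SummaryStats(
        mean_damage_pct=float(np.mean(dmg_net)) * 100.0,
        damage_fractions=np.concatenate(dmg_pool),
        volumes=np.concatenate(vol_pool),
        peripheral_fission_rate=peri / elapsed,
        midzone_fission_rate=mid / elapsed,
        mitophagy_rate=phagy / elapsed,
        mean_n_mitos=float(np.mean(nm)),
        secretion_rate=secr / elapsed,
        n_replicates=len(trajectories),
        window=(burn_in_fraction, 1.0),
    )


def run_replicates(config: SimConfig, replicates: int, base_seed: int,
                   t_end: Optional[float] = None) -> List[Trajectory]:
    return [simulate(config, seed=base_seed + r, t_end=t_end)
            for r in range(replicates)]


def summarize_condition(config: SimConfig, replicates: int, base_seed: int,
                        burn_in_fraction: float = 0.5,
                        t_end: Optional[float] = None) -> SummaryStats:
    trajs = run_replicates(config, replicates, base_seed, t_end=t_end)
    return steady_state_summary(trajs, burn_in_fraction)


def _stats_row(stats: SummaryStats) -> dict:
    return {
        "mean_damage_pct": stats.mean_damage_pct,
        "p5_damage_pct": stats.damage_percentile(5),
        "peripheral_fission_rate": stats.peripheral_fission_rate,
        "midzone_fission_rate": stats.midzone_fission_rate,
        "mitophagy_rate": stats.mitophagy_rate,
        "mean_n_mitos": stats.mean_n_mitos,
        "secretion_rate": stats.secretion_rate,
    }


DEFAULT_ASYM_GRID = (0.0, 0.025, 0.05, 0.075, 0.10)
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))


def factorial_scan(asym_grid: Sequence[float] = DEFAULT_ASYM_GRID,
                   threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
                   replicates: int = 5,
                   base_seed: int = 0,
                   config: Optional[SimConfig] = None,
                   burn_in_fraction: float = 0.5,
                   t_end: Optional[float] = None) -> pd.DataFrame:
    """Full factorial scan over fission asymmetry x damage threshold.

    One row per (asymmetry, threshold, replicate).
    """
    if len(asym_grid) == 0 or len(threshold_grid) == 0:
        raise ValueError("grids must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = config or SimConfig()
    rows = []
    for a in asym_grid:
        for thr in threshold_grid:
            cfg = base.replace(asym_fission=a, Thr_damage=thr)
            for r in range(replicates):
                traj = simulate(cfg, seed=base_seed + r, t_end=t_end)
                stats = steady_state_summary([traj], burn_in_fraction)
                rows.append({"asym_fission": a, "Thr_damage": thr,
                             "replicate": r, **_stats_row(stats)})
    return pd.DataFrame(rows)


_KNOCKDOWN_FIELD = {"fis1": "n_fis1", "mff": "n_mff",
                    "drp1": "drp1_clusters_init"}


def knockdown_scan(protein: str,
                   levels: Sequence[int],
                   replicates: int = 5,
                   base_seed: int = 0,
                   config: Optional[SimConfig] = None,
                   burn_in_fraction: float = 0.5,
                   t_end: Optional[float] = None) -> pd.DataFrame:
    """Scan the abundance of Fis1 or MFF anchor sites or the Drp1 pool.

    For Fis1/MFF the other anchor protein stays at its configured value
    (default 306); for Drp1 the initial cluster count is varied (WT 20000).
    """
    protein = protein.lower()
    if protein not in _KNOCKDOWN_FIELD:
        raise ValueError(f"unknown protein {protein!r}")
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    if any(lv < 0 for lv in levels):
        raise ValueError("levels must be >= 0")
    base = config or SimConfig()
    fld = _KNOCKDOWN_FIELD[protein]
    rows = []
    for lv in levels:
        cfg = base.replace(**{fld: int(lv)})
        for r in range(replicates):
            traj = simulate(cfg, seed=base_seed + r, t_end=t_end)
            stats = steady_state_summary([traj], burn_in_fraction)
            rows.append({"protein": protein, "level": int(lv),
                         "replicate": r, **_stats_row(stats)})
    return pd.DataFrame(rows)


DEFAULT_GLUCOSE_LEVELS = (0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0)
DEFAULT_VARIANTS: Dict[str, dict] = {"wt": {}, "fis1kd": {"n_fis1": 60}}


def dose_response(glucose_levels: Sequence[float] = DEFAULT_GLUCOSE_LEVELS,
                  variants: Optional[Dict[str, dict]] = None,
                  replicates: int = 5,
                  base_seed: int = 0,
                  config: Optional[SimConfig] = None,
                  burn_in_fraction: float = 0.5,
                  t_end: Optional[float] = None) -> pd.DataFrame:
    """Insulin secretion vs glucose for parameter variants (WT, Fis1-KD).

    Adds a ``normalized_rate`` column: secretion relative to the WT mean
    at the highest glucose level.
    """
    if len(glucose_levels) == 0:
        raise ValueError("glucose_levels must be non-empty")
    variants = DEFAULT_VARIANTS if variants is None else variants
    base = config or SimConfig()
    rows = []
    for name, overrides in variants.items():
        for g in glucose_levels:
            cfg = base.replace(glucose_mM=g, **overrides)
            for r in range(replicates):
                traj = simulate(cfg, seed=base_seed + r, t_end=t_end)
                stats = steady_state_summary([traj], burn_in_fraction)
                rows.append({"variant": name, "glucose_mM": g,
                             "replicate": r,
                             "secretion_rate": stats.secretion_rate,
                             "mean_damage_pct": stats.mean_damage_pct})
    df = pd.DataFrame(rows)
    ref_var = "wt" if "wt" in variants else next(iter(variants))
    gmax = max(glucose_levels)
    ref = df[(df.variant == ref_var) & (df.glucose_mM == gmax)
             ].secretion_rate.mean()
    df["normalized_rate"] = df.secretion_rate / ref if ref > 0 else np.nan
    return df


def sobol_sensitivity(param_bounds: Optional[Dict[str, tuple]] = None,
                      n_base: int = 256,
                      base_seed: int = 0,
                      config: Optional[SimConfig] = None,
                      second_order: bool = True,
                      t_end: Optional[float] = None,
                      burn_in_fraction: float = 0.5,
                      model: Optional[Callable[[np.ndarray], float]] = None
                      ) -> SobolResult:
    """Sobol indices of steady-state insulin secretion at 25 mM glucose
    with respect to the five health-coupling parameters.

    ``model`` may override the evaluated function (used by validation
    tests with analytic functions); it receives a parameter vector in the
    order of ``SENSITIVITY_PARAMS``.
    """
    bounds_map = dict(SENSITIVITY_BOUNDS)
    if param_bounds:
        bounds_map.update(param_bounds)
    names = SENSITIVITY_PARAMS
    bounds = np.array([bounds_map[p] for p in names])
    base = (config or SimConfig()).replace(glucose_mM=25.0)

    if model is None:
        def model(x: np.ndarray) -> float:
            cfg = base.replace(**dict(zip(names, map(float, x))))
            traj = simulate(cfg, seed=base_seed, t_end=t_end)
            return steady_state_summary([traj],
                                        burn_in_fraction).secretion_rate

    return sobol_indices(model, bounds, n_base=n_base, seed=base_seed,
                         second_order=second_order, names=names)


def make_kd_ratio_objective(config: Optional[SimConfig] = None,
                            target_ratio: float = 0.60,
                            kd_overrides: Optional[dict] = None,
                            replicates: int = 2,
                            base_seed: int = 0,
                            t_end: Optional[float] = None,
                            param_names: Sequence[str] = SENSITIVITY_PARAMS
                            ) -> Callable[[np.ndarray], float]:
    """Default fitting loss: squared deviation of the knockdown/wild-type
    secretion ratio at 25 mM from ``target_ratio`` plus a penalty when the
    WT dose-response loses its monotone rise from 5 to 25 mM."""
    base = (config or SimConfig()).replace(glucose_mM=25.0)
    kd_overrides = kd_overrides or {"n_fis1": 60}

    def loss(x: np.ndarray) -> float:
        overrides = dict(zip(param_names, map(float, x)))
        wt = base.replace(**overrides)
        kd = wt.replace(**kd_overrides)
        s_wt = summarize_condition(wt, replicates, base_seed,
                                   t_end=t_end).secretion_rate
        s_kd = summarize_condition(kd, replicates, base_seed,
                                   t_end=t_end).secretion_rate
        if s_wt <= 0:
            return 10.0
        ratio = s_kd / s_wt
        low = base.replace(glucose_mM=5.0, **overrides)
        s_low = summarize_condition(low, replicates, base_seed,
                                    t_end=t_end).secretion_rate
        shape_penalty = max(0.0, (s_low - 0.5 * s_wt) / max(s_wt, 1e-9))
        return (ratio - target_ratio) ** 2 + shape_penalty
    return loss


def fit_parameters(objective: Callable[[np.ndarray], float],
                   bounds: Sequence[Sequence[float]],
                   budget: int,
                   base_seed: int = 0,
                   n_particles: int = 12) -> PSOResult:
    """Particle-swarm minimization of a fitting objective (generic hook)."""
    return particle_swarm(objective, bounds, budget=budget, seed=base_seed,
                          n_particles=n_particles)
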