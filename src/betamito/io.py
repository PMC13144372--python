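"""Configuration loading and result writing.

Configs are YAML key/value files validated against :class:`SimConfig`
(unknown keys rejected, constraint violations name the offending key).
Outputs are locale-independent CSV tables (per-mitochondrion snapshots and
cytosolic pools), a JSONL event log, and a JSON run manifest with the
resolved config, seeds and file checksums — enough to re-run the batch
bit-identically with the same code version.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .config import ConfigError, SimConfig
from .engine import Trajectory


def load_config(path) -> SimConfig:
    """Read a YAML config; an empty file yields the full default config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return SimConfig.from_dict(data)


def save_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def pools_frame(traj: Trajectory) -> pd.DataFrame:
    rows = []
    for t, snap in zip(traj.snapshot_times, traj.snapshots):
        rows.append({"t": t, "pyr": snap["pyr"], "atp": snap["atp"],
                     "ca": snap["ca"], "camp": snap["camp"],
                     "drp1_free_u": snap["drp1_free_u"],
                     "drp1_free_p": snap["drp1_free_p"],
                     "drp1_bound": snap["drp1_bound"],
                     "rrp": snap["rrp"], "secreted": snap["secreted"],
                     "n_mitos": snap["n_mitos"],
                     "total_volume": snap["total_volume"],
                     "damage_fraction": snap["damage_fraction"]})
    return pd.DataFrame(rows)


def snapshots_frame(traj: Trajectory) -> pd.DataFrame:
    """One row per mitochondrion per snapshot."""
    u = traj.config.u if traj.config else 100
    rows = []
    for t, snap in zip(traj.snapshot_times, traj.snapshots):
        units = snap["mito_health"] + snap["mito_damage"]
        for k in range(len(units)):
            rows.append({"t": t, "id": int(snap["mito_id"][k]),
                         "v": units[k] / u,
                         "health": int(snap["mito_health"][k]),
                         "damage": int(snap["mito_damage"][k]),
                         "bound_fis1": int(snap["mito_bound_fis1"][k]),
                         "bound_mff": int(snap["mito_bound_mff"][k])})
    return pd.DataFrame(
        rows, columns=["t", "id", "v", "health", "damage",
                       "bound_fis1", "bound_mff"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(trajectories: Sequence[Trajectory], out_dir,
                  tables: Optional[dict] = None,
                  extra_manifest: Optional[dict] = None) -> dict:
    """Write CSV/JSONL outputs plus a manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = time.time()
    files = []

    if trajectories:
        pools = pd.concat(
            [pools_frame(tr).assign(replicate=i)
             for i, tr in enumerate(trajectories)], ignore_index=True)
        pools.to_csv(out / "pools.csv", index=False)
        files.append("pools.csv")
        snaps = pd.concat(
            [snapshots_frame(tr).assign(replicate=i)
             for i, tr in enumerate(trajectories)], ignore_index=True)
        snaps.to_csv(out / "snapshots.csv", index=False)
        files.append("snapshots.csv")
        with open(out / "events.jsonl", "w") as fh:
            for i, tr in enumerate(trajectories):
                for ev in tr.events or []:
                    fh.write(json.dumps({"replicate": i,
                                         **ev.to_json_dict()}) + "\n")
        files.append("events.jsonl")

    for name, df in (tables or {}).items():
        fname = f"{name}.csv"
        df.to_csv(out / fname, index=False)
        files.append(fname)

    cfg = trajectories[0].config if trajectories else None
    manifest = {
        "code_version": __version__,
        "config": cfg.to_dict() if cfg is not None else None,
        "seeds": [tr.seed for tr in trajectories],
        "start_time": start,
        "end_time": time.time(),
        "files": {f: _sha256(out / f) for f in files},
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
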