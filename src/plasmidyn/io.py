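"""File I/O: CSV schemas shared across the package, config loading, and
run manifests.

Column names carry units (x_um, t_s, time_min) so files are unambiguous.
Long-axis coordinates in relative units follow the package convention:
[0, 1], pole at 0, septum at 0.5.

CSV dialects
------------
trajectories : track_id, frame, t_s, x_um, y_um, cell_id
events       : cell_id, marker, t_start_s, t_end_s, rel_pos
profiles     : cell_id, channel, rel_pos, intensity
qpcr         : well, target, ct
counts       : cell_id, n_spots
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .copynum import QPCRPlate
from .profiles import LineProfile
from .repstats import SpotEvent
from .tracking import Trajectory

TRAJECTORY_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "cell_id"]
EVENT_COLUMNS = ["cell_id", "marker", "t_start_s", "t_end_s", "rel_pos"]
PROFILE_COLUMNS = ["cell_id", "channel", "rel_pos", "intensity"]
QPCR_COLUMNS = ["well", "target", "ct"]
COUNT_COLUMNS = ["cell_id", "n_spots"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing column(s): {', '.join(missing)}")


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read a trajectory CSV into per-track objects, sorted by frame.

    Row order in the file does not matter; frames within a track must be
    unique and map to strictly increasing times.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRAJECTORY_COLUMNS[:5], "trajectory")
    if "cell_id" not in df.columns:
        df["cell_id"] = -1
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        if g["frame"].duplicated().any():
            bad = g.loc[g["frame"].duplicated(), "frame"].iloc[0]
            raise ValueError(f"track {tid}: duplicate frame {bad}")
        if np.any(np.diff(g["t_s"].to_numpy()) <= 0):
            raise ValueError(f"track {tid}: times not strictly increasing")
        cid = g["cell_id"].iloc[0]
        out.append(Trajectory(
            track_id=int(tid), times=g["t_s"].to_numpy(),
            x=g["x_um"].to_numpy(), y=g["y_um"].to_numpy(),
            cell_id=None if pd.isna(cid) or cid == -1 else int(cid)))
    return out


def write_trajectories(trajs: list[Trajectory], path: str | Path) -> None:
    rows = []
    for tr in trajs:
        for i in range(len(tr)):
            rows.append((tr.track_id, i, tr.times[i], tr.x[i], tr.y[i],
                         -1 if tr.cell_id is None else tr.cell_id))
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> list[SpotEvent]:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, "events")
    return [SpotEvent(cell_id=int(r.cell_id), marker=str(r.marker),
                      t_start=float(r.t_start_s), t_end=float(r.t_end_s),
                      rel_pos=float(r.rel_pos))
            for r in df.itertuples()]


def write_events(events: list[SpotEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.cell_id, e.marker, e.t_start, e.t_end, e.rel_pos) for e in events],
        columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[LineProfile]:
    df = pd.read_csv(path)
    _require_columns(df, PROFILE_COLUMNS, "profiles")
    out = []
    for (cid, ch), g in df.groupby(["cell_id", "channel"], sort=True):
        g = g.sort_values("rel_pos")
        out.append(LineProfile(cell_id=int(cid), channel=str(ch),
                               rel_pos=g["rel_pos"].to_numpy(),
                               intensity=g["intensity"].to_numpy()))
    return out


def write_profiles(profiles: list[LineProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        rows.extend((p.cell_id, p.channel, rp, it)
                    for rp, it in zip(p.rel_pos, p.intensity))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_qpcr(path: str | Path, eff_chr: float = 2.0,
              eff_pl: float = 2.0) -> QPCRPlate:
    df = pd.read_csv(path)
    _require_columns(df, QPCR_COLUMNS, "qPCR")
    wells = [(str(r.well), str(r.target), float(r.ct)) for r in df.itertuples()]
    return QPCRPlate(wells=wells, eff_chr=eff_chr, eff_pl=eff_pl)


def write_qpcr(plate: QPCRPlate, path: str | Path) -> None:
    pd.DataFrame(plate.wells, columns=QPCR_COLUMNS).to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, "counts")
    return df[COUNT_COLUMNS]


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float image as 16-bit TIFF (clipped to the uint16 range)."""
    import tifffile

    arr = np.clip(np.round(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF image as float64."""
    import tifffile

    return tifffile.imread(str(path)).astype(float)


# ---------------------------------------------------------------------------
# Configuration


def load_config(path: str | Path, cls: type) -> Any:
    """Load a TOML or JSON file into a config dataclass.

    Missing keys take the dataclass defaults; unknown keys are rejected by
    name; values are type-checked against the field annotations.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        import tomllib

        data = tomllib.loads(text)
    if not dataclasses.is_dataclass(cls):
        raise TypeError("cls must be a dataclass")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    clean: dict[str, Any] = {}
    for key, val in data.items():
        if isinstance(val, (bool, int, float, str, list)) or val is None:
            clean[key] = val
        else:
            raise ValueError(f"config key {key!r}: unsupported value type "
                             f"{type(val).__name__}")
    try:
        return cls(**clean)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid config for {cls.__name__}: {exc}") from exc


def dump_config(config: Any, path: str | Path) -> None:
    """Write a config dataclass as JSON (round-trips through load_config)."""
    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=2))


# ---------------------------------------------------------------------------
# Run manifests


def config_hash(config: Any) -> str:
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = config
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir: str | Path, subcommand: str, config: Any = None,
                   seed: int | None = None,
                   inputs: list[str] | None = None) -> Path:
    """Write the single run manifest for an output directory."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config_hash": None if config is None else config_hash(config),
        "seed": seed,
        "inputs": [str(p) for p in (inputs or [])],
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "argv": sys.argv,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
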