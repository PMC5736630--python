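"""File formats: trajectory/feature CSV + JSON sidecars, TIFF stacks, scenarios.

Every writer has a matching reader and all pairs round-trip; the pipeline
relies on this so that each stage is independently re-runnable from disk.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import CorruptFileError, InputError
from .simulate import AgingScenario, SimConfig
from .tracking import FrameStack, TrajectoryEnsemble

TRAJECTORY_COLUMNS = ["particle_id", "frame", "x_um", "y_um"]
FEATURE_CSV_COLUMNS = ["frame", "x_px", "y_px", "mass", "size_px", "ecc"]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_json_atomic(obj, path) -> Path:
    """Write JSON via a temp file + rename so readers never see partial files."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    os.replace(tmp, path)
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_trajectories_csv(ensemble: TrajectoryEnsemble, path,
                           meta_path=None) -> tuple[Path, Path]:
    path = Path(path)
    df = ensemble.to_dataframe()[TRAJECTORY_COLUMNS]
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "fps": ensemble.fps,
        "pixel_size": ensemble.pixel_size,
        "surface_age": ensemble.surface_age,
        "n_trajectories": ensemble.n_trajectories,
    }
    for k, v in ensemble.metadata.items():
        if isinstance(v, (str, int, float, bool, type(None), list, dict)):
            meta[k] = v
    meta_path = Path(meta_path) if meta_path else _meta_path(path)
    write_json_atomic(meta, meta_path)
    return path, meta_path


def read_trajectories_csv(path, meta_path=None) -> TrajectoryEnsemble:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _meta_path(path)
    if not meta_path.exists():
        raise InputError(f"metadata sidecar missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("fps", "pixel_size"):
        if key not in meta:
            raise InputError(f"metadata sidecar {meta_path} missing key {key!r}")
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"trajectory CSV {path} missing columns {missing}")
    extra = {k: v for k, v in meta.items()
             if k not in ("fps", "pixel_size", "surface_age", "n_trajectories")}
    return TrajectoryEnsemble.from_dataframe(
        df, fps=meta["fps"], pixel_size=meta["pixel_size"],
        surface_age=meta.get("surface_age"), metadata=extra)


def write_features_csv(features: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = pd.DataFrame({
        "frame": features["frame"], "x_px": features["x"], "y_px": features["y"],
        "mass": features["mass"], "size_px": features["size"], "ecc": features["ecc"],
    })
    out.to_csv(path, index=False, float_format="%.9g")
    return path


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"feature CSV {path} missing columns {missing}")
    return df.rename(columns={"x_px": "x", "y_px": "y", "size_px": "size"})


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def write_tiff_stack(stack: FrameStack, path, meta_path=None) -> tuple[Path, Path]:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.uint16),
                     photometric="minisblack")
    meta_path = Path(meta_path) if meta_path else _meta_path(path)
    write_json_atomic({"fps": stack.fps, "pixel_size": stack.pixel_size,
                       "bit_depth": stack.bit_depth,
                       "n_frames": stack.n_frames,
                       "shape": list(stack.shape)}, meta_path)
    return path, meta_path


def read_tiff_stack(path, meta_path=None) -> FrameStack:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _meta_path(path)
    if not meta_path.exists():
        raise InputError(f"metadata sidecar missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("fps", "pixel_size"):
        if key not in meta:
            raise InputError(f"metadata sidecar {meta_path} missing key {key!r}")
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various decode errors
        raise CorruptFileError(f"cannot decode TIFF {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames, fps=meta["fps"], pixel_size=meta["pixel_size"],
                      bit_depth=meta.get("bit_depth", 16))


# ---------------------------------------------------------------------------
# Scenarios and analysis outputs
# ---------------------------------------------------------------------------

def write_scenario_json(scenario: AgingScenario, path) -> Path:
    obj = {"name": scenario.name,
           "stanzas": [{"age_s": age, "config": cfg.to_dict()}
                       for age, cfg in scenario.stanzas]}
    return write_json_atomic(obj, path)


def read_scenario_json(path) -> AgingScenario:
    obj = json.loads(Path(path).read_text())
    try:
        stanzas = [(float(s["age_s"]), SimConfig.from_dict(s["config"]))
                   for s in obj["stanzas"]]
        return AgingScenario(name=obj["name"], stanzas=stanzas)
    except (KeyError, TypeError) as exc:
        raise InputError(f"malformed scenario file {path}: {exc}") from exc


def write_msd_csv(curve, path) -> Path:
    path = Path(path)
    pd.DataFrame({"lag_s": curve.lag_s, "msd_um2": curve.msd,
                  "n_traj": curve.n_traj}).to_csv(path, index=False,
                                                  float_format="%.9g")
    return path


def write_timecourse_outputs(result, out_dir, stem="timecourse") -> dict[str, Path]:
    """Per-age summary CSV + transition JSON for a TimecourseResult."""
    out_dir = Path(out_dir)
    rows = [{"age_s": s.surface_age, "n": s.fit.exponent, "d_um": s.fit.d,
             "regime": s.label.regime, "D_app_um2_s": s.apparent_diffusivity,
             "count": s.n_trajectories, "r_squared": s.fit.r_squared}
            for s in result.summaries]
    summary_csv = out_dir / f"{stem}_summary.csv"
    pd.DataFrame(rows).to_csv(summary_csv, index=False, float_format="%.9g")
    tc_json = write_json_atomic({
        "transition_age_s": result.transition_age,
        "subdiffusive_onset_age_s": result.subdiffusive_onset_age,
        "skipped_ages_s": result.skipped_ages,
        "params": result.params,
        "regimes": {str(s.surface_age): s.label.regime for s in result.summaries},
    }, out_dir / f"{stem}.json")
    return {"summary_csv": summary_csv, "timecourse_json": tc_json}
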