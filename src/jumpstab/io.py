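"""File readers and writers.

All tables are RFC-4180 CSV with ``.`` decimal separator and UTF-8 text;
angles are degrees in every file and radians internally.  Simulation
results carry a JSON metadata sidecar (``<name>.meta.json``) recording the
time step, seed, preset, morphology and package version so a run can be
reproduced from its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import RESULT_COLUMNS, SimResult
from .kinematics import JointTrajectorySet
from .morphology import MorphologyParams

TRAJECTORY_COLUMNS = ["time_s", "hip_deg", "knee_deg", "ankle_deg", "tmt_deg"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending column or row."""


def read_trajectory(path) -> JointTrajectorySet:
    """Read a joint-trajectory CSV (columns ``time_s,hip_deg,knee_deg,ankle_deg,tmt_deg``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: could not parse CSV: {exc}") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    df = df[TRAJECTORY_COLUMNS]
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ParseError(f"{path}: non-numeric or missing value in data row {bad[0] + 2} "
                         "(counting the header as row 1)")
    if len(df) < 4:
        raise ParseError(f"{path}: need at least 4 knot rows for cubic-spline "
                         f"interpolation, got {len(df)}")
    times = df["time_s"].to_numpy(float)
    steps = np.diff(times)
    if np.any(steps <= 0):
        row = int(np.nonzero(steps <= 0)[0][0]) + 3
        raise ParseError(f"{path}: time_s must be strictly increasing (violated at row {row})")
    angles = df[["hip_deg", "knee_deg", "ankle_deg", "tmt_deg"]].to_numpy(float)
    return JointTrajectorySet.from_degrees(times, angles)


def write_trajectory(traj: JointTrajectorySet, path) -> None:
    df = pd.DataFrame(traj.knot_angles_deg, columns=["hip_deg", "knee_deg", "ankle_deg", "tmt_deg"])
    df.insert(0, "time_s", traj.knot_times)
    # %.17g preserves float64 exactly, so write -> read is lossless
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def _read_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_morphology(path) -> MorphologyParams:
    """Read a morphology config (JSON or YAML, keys matching the field names)."""
    return MorphologyParams.from_config(_read_structured(path))


def write_morphology(morph: MorphologyParams, path) -> None:
    path = Path(path)
    cfg = morph.to_config()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def write_result(result: SimResult, path, decimate: int = 1) -> None:
    """Write a simulation result CSV plus its JSON metadata sidecar."""
    path = Path(path)
    df = result.data.iloc[::max(1, int(decimate))]
    df.to_csv(path, index=False, lineterminator="\n")
    meta = dict(result.meta)
    meta.update({
        "mode": result.mode,
        "morphology": result.morph.to_config(),
        "package_version": __version__,
        "decimate": int(decimate),
    })
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_result(path) -> SimResult:
    """Read a result CSV written by :func:`write_result` (sidecar required for mode/morphology)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing result column(s) {missing}")
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise ParseError(f"{path}: metadata sidecar {meta_path.name} not found")
    meta = json.loads(meta_path.read_text())
    morph = MorphologyParams.from_config(meta["morphology"])
    mode = meta.get("mode", "ground")
    return SimResult(df[RESULT_COLUMNS], morph, mode, meta)
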