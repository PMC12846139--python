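"""File formats: TRC and CSV marker/motion/force tables, YAML configs.

TRC is the standard motion-capture text format: positions are stored in
millimetres (per the format convention) and converted to metres on read.
All other tables are plain CSV.  Configuration is a single YAML document
covering every stage of the pipeline; the global seed recorded there
makes any run reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import DOF_NAMES, MARKER_NAMES, MarkerTrajectory, MotionTrajectory
from .staticopt import ForceSeries, SOConfig

__all__ = [
    "read_markers",
    "write_trc",
    "read_trc",
    "write_markers_csv",
    "read_markers_csv",
    "write_motion_csv",
    "read_motion_csv",
    "write_forces_csv",
    "read_forces_csv",
    "write_forces_npz",
    "read_forces_npz",
    "write_semg_csv",
    "read_semg_csv",
    "save_model",
    "load_model",
    "RunConfig",
    "load_config",
    "save_config",
]

#: common alternative marker labels mapped onto the canonical TP/LH/RH
DEFAULT_MARKER_ALIASES = {
    "TP": "TP", "TOP": "TP", "TOP_HEAD": "TP",
    "LH": "LH", "LEFT_HEAD": "LH",
    "RH": "RH", "RIGHT_HEAD": "RH",
}


def write_trc(path, traj: MarkerTrajectory) -> None:
    """Write a marker trajectory as TRC (mm units, tab-separated)."""
    path = Path(path)
    fs = 1.0 / float(traj.times[1] - traj.times[0])
    n = traj.times.shape[0]
    names = traj.marker_names
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{fs:.2f}\t{fs:.2f}\t{n}\t{len(names)}\tmm\t{fs:.2f}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\n")
        fh.write("\t\t" + "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names))) + "\n")
        for k in range(n):
            coords = (traj.positions[k] * 1000.0).ravel()
            fh.write(f"{k+1}\t{traj.times[k]:.5f}\t"
                     + "\t".join(f"{c:.5f}" for c in coords) + "\n")


def read_trc(path, aliases: dict | None = None) -> MarkerTrajectory:
    """Read a TRC file; maps marker labels to TP/LH/RH via the alias table."""
    aliases = {**DEFAULT_MARKER_ALIASES, **(aliases or {})}
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ValueError("malformed TRC: too few header lines")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    meta = dict(zip(header_keys, header_vals))
    try:
        fs = float(meta["DataRate"])
        units = meta["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise ValueError("malformed TRC header (DataRate/Units)") from exc
    unit_to_m = {"mm": 1e-3, "m": 1.0, "cm": 1e-2}.get(units)
    if unit_to_m is None:
        raise ValueError(f"unsupported TRC units {units!r}")
    labels = [s for s in lines[3].split("\t")[2:] if s.strip()]
    canon = {}
    for i, lab in enumerate(labels):
        key = aliases.get(lab.strip().upper(), aliases.get(lab.strip()))
        if key:
            canon[key] = i
    missing = [m for m in MARKER_NAMES if m not in canon]
    if missing:
        raise ValueError(f"TRC file missing marker column(s): {missing}")
    rows = [l.split("\t") for l in lines[5:] if l.strip()]
    times = np.array([float(r[1]) for r in rows])
    data = np.array([[float(v) for v in r[2:2 + 3 * len(labels)]] for r in rows])
    dt = np.diff(times)
    if times.size > 1 and not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise ValueError("non-uniform timestamps in TRC file")
    if times.size > 1 and abs(1.0 / dt[0] - fs) > 0.5:
        raise ValueError("TRC DataRate disagrees with timestamps")
    pos = np.empty((times.size, 3, 3))
    for k, m in enumerate(MARKER_NAMES):
        i = canon[m]
        pos[:, k, :] = data[:, 3 * i:3 * i + 3] * unit_to_m
    return MarkerTrajectory(times, pos)


def read_markers(path, fmt: str | None = None, aliases: dict | None = None
                 ) -> MarkerTrajectory:
    """Read markers from TRC or CSV, inferring the format from the suffix."""
    path = Path(path)
    fmt = fmt or ("trc" if path.suffix.lower() == ".trc" else "csv")
    if fmt == "trc":
        return read_trc(path, aliases)
    if fmt == "csv":
        return read_markers_csv(path)
    raise ValueError(f"unknown marker format {fmt!r}")


def write_markers_csv(path, traj: MarkerTrajectory) -> None:
    cols = {"time": traj.times}
    for k, m in enumerate(traj.marker_names):
        for a, ax in enumerate("xyz"):
            cols[f"{m}_{ax}"] = traj.positions[:, k, a]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_markers_csv(path) -> MarkerTrajectory:
    df = pd.read_csv(path)
    missing = [m for m in MARKER_NAMES
               if any(f"{m}_{ax}" not in df.columns for ax in "xyz")]
    if missing:
        raise ValueError(f"CSV missing marker column(s): {missing}")
    pos = np.stack(
        [df[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy() for m in MARKER_NAMES],
        axis=1,
    )
    return MarkerTrajectory(df["time"].to_numpy(), pos)


def write_motion_csv(path, motion: MotionTrajectory) -> None:
    df = pd.DataFrame(motion.q, columns=list(motion.dof_names))
    df.insert(0, "time", motion.times)
    df.to_csv(path, index=False)


def read_motion_csv(path) -> MotionTrajectory:
    df = pd.read_csv(path)
    names = [c for c in df.columns if c != "time"]
    return MotionTrajectory(df["time"].to_numpy(), df[names].to_numpy(),
                            tuple(names))


def write_forces_csv(path, forces: ForceSeries) -> None:
    forces.to_frame().to_csv(path, index=False)


def read_forces_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_forces_npz(path, forces: ForceSeries) -> None:
    """Compact binary container for large force runs."""
    np.savez_compressed(
        path, times=forces.times, forces=forces.forces,
        residuals=forces.residuals, status=np.array(forces.status),
        muscle_names=np.array(forces.muscle_names),
    )


def read_forces_npz(path) -> ForceSeries:
    d = np.load(path, allow_pickle=False)
    return ForceSeries(d["times"], d["forces"], d["residuals"],
                       [str(s) for s in d["status"]],
                       [str(m) for m in d["muscle_names"]])


# --------------------------------------------------------------------------
# sEMG channels
# --------------------------------------------------------------------------

def write_semg_csv(path, recordings) -> None:
    """CSV with a commented header carrying fs and per-channel MVC."""
    from .activation import EMGRecording  # noqa: F401  (type reference)

    fs = recordings[0].fs
    n = len(recordings[0].samples)
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        for rec in recordings:
            fh.write(f"# mvc_{rec.channel}={rec.mvc}\n")
        fh.write("time," + ",".join(r.channel for r in recordings) + "\n")
        t = np.arange(n) / fs
        data = np.column_stack([r.samples for r in recordings])
        for k in range(n):
            fh.write(f"{t[k]:.6f}," + ",".join(f"{v:.6f}" for v in data[k]) + "\n")


def read_semg_csv(path):
    from .activation import EMGRecording

    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
            body_start = i + 1
        else:
            break
    import io as _io
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    fs = meta.get("fs", 1000.0)
    recs = []
    for col in df.columns:
        if col == "time":
            continue
        mvc = meta.get(f"mvc_{col}", 1.0)
        recs.append(EMGRecording(col, df[col].to_numpy(), fs, mvc))
    return recs


# --------------------------------------------------------------------------
# model serialization
# --------------------------------------------------------------------------

def save_model(path, model) -> None:
    """Serialize a neck model to a structured YAML document."""
    from .model import NeckModel  # noqa: F401

    doc = {
        "profile": {
            "head_mass": float(model.profile.head_mass),
            "shoulder_width": float(model.profile.shoulder_width),
            "neck_length": float(model.profile.neck_length),
        },
        "gravity": float(model.gravity),
        "skull_base_height": float(model.skull_base_height),
        "passive_stiffness": model.passive_stiffness.tolist(),
        "passive_damping": model.passive_damping.tolist(),
        "joints": [
            {"name": j.name, "axis": j.axis.tolist(), "offset": j.offset.tolist()}
            for j in model.joints
        ],
        "bodies": [
            {"name": b.name, "frame": b.frame, "mass": float(b.mass),
             "com": b.com.tolist(), "inertia": b.inertia.tolist()}
            for b in model.bodies
        ],
        "markers": {k: v.tolist() for k, v in model.marker_offsets.items()},
        "muscles": [
            {"name": m.name, "side": m.side, "depth_class": m.depth_class,
             "origin_body": m.origin_body, "origin": m.origin.tolist(),
             "insertion_body": m.insertion_body,
             "insertion": m.insertion.tolist(), "f_max": float(m.f_max),
             "partner": m.partner,
             "origin_shoulder_scaled": bool(m.origin_shoulder_scaled),
             "rest_length": float(m.rest_length)}
            for m in model.muscles
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path):
    from .anthropometry import AnthroProfile
    from .model import Body, Joint, MuscleSpec, NeckModel

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return NeckModel(
        joints=[Joint(j["name"], np.array(j["axis"]), np.array(j["offset"]))
                for j in doc["joints"]],
        bodies=[Body(b["name"], b["frame"], b["mass"], np.array(b["com"]),
                     np.array(b["inertia"])) for b in doc["bodies"]],
        muscles=[MuscleSpec(m["name"], m["side"], m["depth_class"],
                            m["origin_body"], np.array(m["origin"]),
                            m["insertion_body"], np.array(m["insertion"]),
                            m["f_max"], m["partner"],
                            m["origin_shoulder_scaled"], m["rest_length"])
                 for m in doc["muscles"]],
        marker_offsets={k: np.array(v) for k, v in doc["markers"].items()},
        skull_base_height=doc["skull_base_height"],
        passive_stiffness=np.array(doc["passive_stiffness"]),
        passive_damping=np.array(doc["passive_damping"]),
        gravity=doc["gravity"],
        profile=AnthroProfile(**doc["profile"]),
    )


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Single-document configuration for the end-to-end pipeline."""

    seed: int = 0
    out_dir: str = "neckforce_run"
    n_models: int = 20
    population_mean: list | None = None      # defaults to packaged statistics
    population_cov: list | None = None
    muscle_set: str = "reduced"              # "reduced" (16) or "full" (72)
    motions: list = field(default_factory=lambda: [
        {"motion_type": "flexion_extension", "duration": 5.0, "cycles": 2},
        {"motion_type": "lateral_bending", "duration": 5.0, "cycles": 2},
        {"motion_type": "axial_rotation", "duration": 5.0, "cycles": 2},
        {"motion_type": "combined", "duration": 6.0, "cycles": 2},
    ])
    so: dict = field(default_factory=dict)   # SOConfig overrides
    training: dict = field(default_factory=dict)
    envelope_alpha: float = float("inf")
    iou_resolution: int = 48
    patient_sectors: list = field(default_factory=lambda: ["flexion", "right_rot"])
    patient_factor: float = 0.6

    def so_config(self) -> SOConfig:
        return SOConfig(**self.so)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)


def save_config(path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
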