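"""Synthetic neck-motion generation and DTW alignment/averaging.

Standardized motions (flexion–extension, lateral bending, axial rotation,
combined, spontaneous) are generated as raised-cosine cycles: each cycle
sweeps neutral → +amplitude → neutral → −amplitude → neutral with zero
velocity at every turning point, matching tasks that start and stop at
rest.  The commanded angle of each physiological direction is split
evenly between the lower and upper articulations.

"Restricted" variants emulate a patient who cannot reach part of the
range of motion: excursions into chosen direction sectors (signed
half-ranges, e.g. ``"right_rot"``) are attenuated by a factor in (0, 1],
while all other directions are untouched.

Multiple recordings of the same task can be fused with classical dynamic
time warping: all series are aligned to the medoid (minimum total
pairwise DTW distance, Euclidean local cost, symmetric steps, no window)
and averaged point-wise on the medoid's timebase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import DOF_NAMES, MotionTrajectory

__all__ = [
    "MotionSpec",
    "SECTORS",
    "generate_motion",
    "restrict_motion",
    "dtw_distance",
    "dtw_path",
    "dtw_average",
]

MOTION_TYPES = ("flexion_extension", "lateral_bending", "axial_rotation",
                "combined", "spontaneous")

#: physiological bounds on the total commanded amplitude per direction (rad)
ROM_BOUNDS = {"fe": 1.2, "lb": 0.9, "ar": 1.6}

#: direction sector -> (direction key, sign of the restricted half-range)
SECTORS = {
    "flexion": ("fe", +1), "extension": ("fe", -1),
    "left_bend": ("lb", +1), "right_bend": ("lb", -1),
    "left_rot": ("ar", +1), "right_rot": ("ar", -1),
}

_DOF_COLUMNS = {"fe": (0, 3), "lb": (1, 4), "ar": (2, 5)}


@dataclass(frozen=True)
class MotionSpec:
    motion_type: str = "flexion_extension"
    amplitudes: dict | None = None          # {"fe": rad, "lb": rad, "ar": rad}
    duration: float = 5.0                   # s
    fs: float = 100.0                       # Hz
    cycles: int = 2
    restriction: tuple | None = None        # (sector names, attenuation factor)
    seed: int = 0                           # used by "spontaneous"

    def __post_init__(self) -> None:
        if self.motion_type not in MOTION_TYPES:
            raise ValueError(f"unknown motion type {self.motion_type!r}")
        if self.fs <= 0 or self.duration <= 0 or self.cycles < 1:
            raise ValueError("fs, duration and cycles must be positive")
        amps = dict(self.amplitudes or {"fe": 0.8, "lb": 0.6, "ar": 1.0})
        for k, a in amps.items():
            if a < 0 or a > ROM_BOUNDS[k]:
                raise ValueError(f"amplitude {k}={a} outside physiological bounds")
        object.__setattr__(self, "amplitudes", amps)
        if self.restriction is not None:
            sectors, factor = self.restriction
            if not sectors:
                raise ValueError("restriction sector set must be nonempty")
            if not 0 < factor <= 1:
                raise ValueError("attenuation factor must be in (0, 1]")
            for s in sectors:
                if s not in SECTORS:
                    raise ValueError(f"unknown sector {s!r}")


def _raised_cosine_cycle(phase: np.ndarray) -> np.ndarray:
    """Smooth 0 → +1 → 0 → −1 → 0 waveform over phase ∈ [0, 1)."""
    up = 0.5 * (1.0 - np.cos(4.0 * np.pi * phase))
    return np.where(phase < 0.5, up, -up)


def generate_motion(spec: MotionSpec) -> MotionTrajectory:
    """Generate a joint-angle trajectory for a motion specification."""
    n = int(round(spec.duration * spec.fs))
    times = np.arange(n) / spec.fs
    phase = (times * spec.cycles / spec.duration) % 1.0
    q = np.zeros((n, len(DOF_NAMES)))

    amps = spec.amplitudes
    if spec.motion_type == "flexion_extension":
        _set_direction(q, "fe", amps["fe"] * _raised_cosine_cycle(phase))
    elif spec.motion_type == "lateral_bending":
        _set_direction(q, "lb", amps["lb"] * _raised_cosine_cycle(phase))
    elif spec.motion_type == "axial_rotation":
        _set_direction(q, "ar", amps["ar"] * _raised_cosine_cycle(phase))
    elif spec.motion_type == "combined":
        # simultaneous half-amplitude flexion and rotation, 90° out of phase
        _set_direction(q, "fe", 0.5 * amps["fe"] * _raised_cosine_cycle(phase))
        _set_direction(q, "ar", 0.5 * amps["ar"]
                       * _raised_cosine_cycle((phase + 0.25) % 1.0))
    elif spec.motion_type == "spontaneous":
        rng = np.random.default_rng(spec.seed)
        taper = np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2
        for key in ("fe", "lb", "ar"):
            freqs = rng.uniform(0.1, 0.5, size=4)       # Hz, band-limited
            phases = rng.uniform(0, 2 * np.pi, size=4)
            wgts = rng.uniform(0.3, 1.0, size=4)
            sig = np.sum(
                wgts[:, None] * np.sin(2 * np.pi * freqs[:, None] * times
                                       + phases[:, None]),
                axis=0,
            )
            peak = np.abs(sig).max()
            if peak > 0:
                sig = sig / peak * amps[key] * rng.uniform(0.5, 1.0)
            _set_direction(q, key, sig * taper)

    if spec.restriction is not None:
        sectors, factor = spec.restriction
        for s in sectors:
            key, sign = SECTORS[s]
            for col in _DOF_COLUMNS[key]:
                mask = np.sign(q[:, col]) == sign
                q[mask, col] *= factor
    return MotionTrajectory(times, q)


def _set_direction(q: np.ndarray, key: str, signal: np.ndarray) -> None:
    for col in _DOF_COLUMNS[key]:
        q[:, col] = 0.5 * signal             # even split across articulations


def restrict_motion(spec: MotionSpec, sectors, factor: float) -> MotionSpec:
    """Return a spec whose excursions into ``sectors`` are attenuated."""
    sectors = tuple(sectors) if not isinstance(sectors, str) else (sectors,)
    return replace(spec, restriction=(sectors, float(factor)))


# --------------------------------------------------------------------------
# dynamic time warping
# --------------------------------------------------------------------------

def _as_matrix(x) -> np.ndarray:
    if isinstance(x, MotionTrajectory):
        return x.q
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _dtw_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    n, m = cost.shape
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = D[i - 1]
        for j in range(1, m + 1):
            D[i, j] = cost[i - 1, j - 1] + min(row[j], row[j - 1], D[i, j - 1])
    return D


def dtw_distance(a, b) -> float:
    """Classical DTW distance (Euclidean local cost, symmetric steps)."""
    a, b = _as_matrix(a), _as_matrix(b)
    return float(_dtw_matrix(a, b)[-1, -1])


def dtw_path(a, b) -> list[tuple[int, int]]:
    """Optimal warping path as (index into a, index into b) pairs."""
    a, b = _as_matrix(a), _as_matrix(b)
    D = _dtw_matrix(a, b)
    i, j = a.shape[0], b.shape[0]
    path = [(i - 1, j - 1)]
    while (i, j) != (1, 1):
        steps = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        vals = [D[s] for s in steps]
        i, j = steps[int(np.argmin(vals))]
        path.append((i - 1, j - 1))
    path.reverse()
    return path


def dtw_average(trajectories: list[MotionTrajectory]) -> MotionTrajectory:
    """Medoid-referenced DTW average of joint-angle trajectories.

    All inputs are warped onto the medoid's timebase via their optimal
    paths (frames matched to the same medoid index are averaged), then
    averaged point-wise across trajectories.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    d = trajectories[0].q.shape[1]
    if any(t.q.shape[1] != d for t in trajectories):
        raise ValueError("all trajectories must share the DOF count")

    k = len(trajectories)
    totals = np.zeros(k)
    for i in range(k):
        for j in range(i + 1, k):
            dist = dtw_distance(trajectories[i], trajectories[j])
            totals[i] += dist
            totals[j] += dist
    medoid = int(np.argmin(totals))
    ref = trajectories[medoid]

    warped = np.zeros((k, ref.n_frames, d))
    for t, traj in enumerate(trajectories):
        path = dtw_path(ref, traj)
        sums = np.zeros((ref.n_frames, d))
        counts = np.zeros(ref.n_frames)
        for i_ref, j_other in path:
            sums[i_ref] += traj.q[j_other]
            counts[i_ref] += 1
        warped[t] = sums / counts[:, None]
    return MotionTrajectory(ref.times.copy(), warped.mean(axis=0), ref.dof_names)
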