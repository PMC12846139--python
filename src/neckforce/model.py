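"""Parametric rigid-body head–neck linkage with straight-line muscles.

The cervical column is reduced to a serial chain of two lumped
articulations — a lower (T1/mid-cervical) and an upper (mid-cervical/
skull) joint — each with three rotational degrees of freedom ordered as
(flexion–extension, lateral bending, axial rotation).  Two rigid bodies
carry mass: the lower cervical segment and the head (which includes the
upper cervical column).  This reduction keeps the full structure of the
rigid-body equations of motion

    M(q) q̈ + C(q, q̇) q̇ + G(q) = R(q) f + τ_passive + Jᵀ F_ext

while remaining fully specifiable from three anthropometric parameters
(head mass, shoulder width, neck length).

Conventions
-----------
* torso-fixed frame, origin at the chain base (T1): x anterior, y left,
  z superior; gravity acts along −z.
* angles in radians; positive flexion tips the head anterior (rotation
  about +y), positive lateral bending tips it to the left (about +x),
  positive axial rotation turns it to the left (about +z).
* moment arm entry (j, i) equals −∂l_i/∂q_j, so a muscle with a positive
  entry produces a positive moment about DOF j when it pulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anthropometry import AnthroProfile
from .muscles import BASE_MUSCLE_NAMES, MUSCLE_GEOMETRY

__all__ = [
    "Joint",
    "Body",
    "MuscleSpec",
    "NeckModel",
    "MotionTrajectory",
    "MarkerTrajectory",
    "ExternalLoad",
    "DOF_NAMES",
    "MARKER_NAMES",
    "build_default_model",
    "scale_model",
    "forward_markers",
    "markers_for_motion",
    "muscle_lengths",
    "muscle_length_rates",
    "moment_arm_matrix",
    "inverse_dynamics",
    "mass_matrix",
    "derive_kinematics",
    "mechanical_energy",
]

DOF_NAMES = ("lower_fe", "lower_lb", "lower_ar", "upper_fe", "upper_lb", "upper_ar")
MARKER_NAMES = ("TP", "LH", "RH")

_AXES = {"fe": np.array([0.0, 1.0, 0.0]), "lb": np.array([1.0, 0.0, 0.0]),
         "ar": np.array([0.0, 0.0, 1.0])}

#: default mean-population profile used for the packaged base model
_MEAN_PROFILE = AnthroProfile(6.377, 39.920, 10.730)


@dataclass(frozen=True)
class Joint:
    name: str
    axis: np.ndarray        # rotation axis, parent frame
    offset: np.ndarray      # translation from parent frame origin, parent frame


@dataclass(frozen=True)
class Body:
    name: str
    frame: int              # 1-based index of the joint frame the body is fixed to
    mass: float             # kg
    com: np.ndarray         # centre of mass, body frame (m)
    inertia: np.ndarray     # 3x3 inertia about the COM, body frame (kg m^2)


@dataclass(frozen=True)
class MuscleSpec:
    name: str
    side: str               # "right" | "left"
    depth_class: str        # "deep" | "superficial"
    origin_body: str        # "torso" | body name
    origin: np.ndarray      # body frame (m)
    insertion_body: str
    insertion: np.ndarray
    f_max: float            # N
    partner: str
    origin_shoulder_scaled: bool = False
    rest_length: float = 0.0


@dataclass(frozen=True)
class ExternalLoad:
    body: str = "head"
    force: np.ndarray = field(default_factory=lambda: np.zeros(3))   # N, torso frame
    moment: np.ndarray = field(default_factory=lambda: np.zeros(3))  # N m, torso frame


@dataclass
class NeckModel:
    joints: list[Joint]
    bodies: list[Body]
    muscles: list[MuscleSpec]
    marker_offsets: dict[str, np.ndarray]     # head-body frame (m)
    skull_base_height: float                  # z of the skull base in the head frame (m)
    passive_stiffness: np.ndarray             # N m / rad, per DOF
    passive_damping: np.ndarray               # N m s / rad, per DOF
    gravity: float = 9.81
    profile: AnthroProfile = _MEAN_PROFILE

    @property
    def ndof(self) -> int:
        return len(self.joints)

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    @property
    def f_max(self) -> np.ndarray:
        return np.array([m.f_max for m in self.muscles])

    def body_frame(self, name: str) -> int:
        if name == "torso":
            return 0
        for b in self.bodies:
            if b.name == name:
                return b.frame
        raise KeyError(f"unknown body {name!r}")

    def chain_length(self) -> float:
        return float(sum(j.offset[2] for j in self.joints) + self.skull_base_height)


@dataclass
class MotionTrajectory:
    """Joint-angle time series, uniformly sampled."""

    times: np.ndarray
    q: np.ndarray                              # frames x ndof, rad
    dof_names: tuple[str, ...] = DOF_NAMES
    qd: np.ndarray | None = None
    qdd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        if self.q.shape[0] != self.times.shape[0]:
            raise ValueError("times and q frame counts differ")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("joint angles must be finite")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]


@dataclass
class MarkerTrajectory:
    """3-marker position time series in the torso-fixed frame (m)."""

    times: np.ndarray
    positions: np.ndarray                      # frames x 3 markers x 3 coords
    marker_names: tuple[str, ...] = MARKER_NAMES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.times.shape[0], len(self.marker_names), 3):
            raise ValueError("positions must be frames x markers x 3")


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------

def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def build_default_model(
    profile: AnthroProfile | None = None,
    muscle_names: list[str] | None = None,
    passive_stiffness: float = 0.5,
    passive_damping: float = 0.01,
) -> NeckModel:
    """Construct the packaged head–neck model for an anthropometric profile.

    ``muscle_names`` selects base (right-side) muscle names; the bilateral
    partner is always included.  Default: all 36 pairs (72 muscles).
    """
    profile = profile or _MEAN_PROFILE
    Lc = profile.neck_length / 100.0           # cm -> m: C7–EOP chain length
    W = profile.shoulder_width / 100.0
    L1 = 0.5 * Lc
    L2 = 0.5 * Lc
    Wh = 0.5 * W

    joints = []
    for art, off in (("lower", np.zeros(3)), ("upper", np.array([0.0, 0.0, L1]))):
        for k, dof in enumerate(("fe", "lb", "ar")):
            joints.append(Joint(f"{art}_{dof}", _AXES[dof].copy(),
                                off if k == 0 else np.zeros(3)))

    m_neck, r_neck = 1.2, 0.05
    I_neck = np.diag([
        m_neck * (3 * r_neck**2 + L1**2) / 12.0,
        m_neck * (3 * r_neck**2 + L1**2) / 12.0,
        m_neck * r_neck**2 / 2.0,
    ])
    m_head, r_head = profile.head_mass, 0.09
    I_head = np.eye(3) * (0.4 * m_head * r_head**2)
    bodies = [
        Body("neck", 3, m_neck, np.array([0.0, 0.0, L1 / 2.0]), I_neck),
        Body("head", 6, m_head, np.array([0.0, 0.0, L2 + 0.03]), I_head),
    ]

    names = muscle_names if muscle_names is not None else BASE_MUSCLE_NAMES
    muscles: list[MuscleSpec] = []
    for base in names:
        ob, ofun, ib, ifun, fmax, depth, sh = MUSCLE_GEOMETRY[base]
        org = np.array(ofun(L1, L2, Wh))
        ins = np.array(ifun(L1, L2, Wh))
        muscles.append(MuscleSpec(base, "right", depth, ob, org, ib, ins,
                                  fmax, base + "_L", sh))
        mirror = np.array([1.0, -1.0, 1.0])
        muscles.append(MuscleSpec(base + "_L", "left", depth, ob, org * mirror,
                                  ib, ins * mirror, fmax, base, sh))

    marker_offsets = {
        "TP": np.array([0.0, 0.0, L2 + 0.11]),
        "LH": np.array([0.0, 0.085, L2 + 0.03]),
        "RH": np.array([0.0, -0.085, L2 + 0.03]),
    }
    model = NeckModel(
        joints=joints,
        bodies=bodies,
        muscles=muscles,
        marker_offsets=marker_offsets,
        skull_base_height=L2,
        passive_stiffness=np.full(6, passive_stiffness),
        passive_damping=np.full(6, passive_damping),
        profile=profile,
    )
    _set_rest_lengths(model)
    return model


def _set_rest_lengths(model: NeckModel) -> None:
    lengths = muscle_lengths(model, np.zeros(model.ndof))
    model.muscles = [replace(m, rest_length=float(l))
                     for m, l in zip(model.muscles, lengths)]


def scale_model(base: NeckModel, profile: AnthroProfile) -> NeckModel:
    """Scale a model to a new anthropometric profile.

    The chain (and every z coordinate expressed in a moving-body frame)
    scales with neck length; shoulder-anchored origins scale laterally
    with shoulder width; head mass and inertia scale with the head-mass
    ratio.  Muscle rest lengths are recomputed from the scaled geometry.
    """
    rl = profile.neck_length / base.profile.neck_length
    rw = profile.shoulder_width / base.profile.shoulder_width
    rm = profile.head_mass / base.profile.head_mass

    joints = [replace(j, offset=j.offset * np.array([1.0, 1.0, rl]))
              for j in base.joints]
    bodies = []
    for b in base.bodies:
        com = b.com * np.array([1.0, 1.0, rl])
        mass, inertia = b.mass, b.inertia
        if b.name == "head":
            mass, inertia = b.mass * rm, b.inertia * rm
        bodies.append(replace(b, mass=mass, com=com, inertia=inertia))

    zscale = np.array([1.0, 1.0, rl])
    muscles = []
    for m in base.muscles:
        org = m.origin.copy()
        if m.origin_body != "torso":
            org = org * zscale
        elif m.origin_shoulder_scaled:
            org = org * np.array([1.0, rw, 1.0])
        ins = m.insertion * zscale if m.insertion_body != "torso" else m.insertion.copy()
        muscles.append(replace(m, origin=org, insertion=ins))

    scaled = NeckModel(
        joints=joints,
        bodies=bodies,
        muscles=muscles,
        marker_offsets={k: v * zscale for k, v in base.marker_offsets.items()},
        skull_base_height=base.skull_base_height * rl,
        passive_stiffness=base.passive_stiffness.copy(),
        passive_damping=base.passive_damping.copy(),
        gravity=base.gravity,
        profile=profile,
    )
    _set_rest_lengths(scaled)
    return scaled


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def _frames(model: NeckModel, q: np.ndarray):
    """World rotation, joint origin and world joint axis for every frame."""
    q = np.asarray(q, dtype=float)
    if q.shape != (model.ndof,):
        raise ValueError(f"q must have length {model.ndof}")
    R = np.eye(3)
    p = np.zeros(3)
    Rs, ps, axes = [], [], []
    for j, joint in enumerate(model.joints):
        p = p + R @ joint.offset
        axis_w = R @ joint.axis
        R = R @ _rot(joint.axis, q[j])
        Rs.append(R)
        ps.append(p.copy())
        axes.append(axis_w)
    return Rs, ps, axes


def _point_world(model: NeckModel, Rs, ps, body: str, local: np.ndarray) -> np.ndarray:
    f = model.body_frame(body)
    if f == 0:
        return np.asarray(local, dtype=float)
    return ps[f - 1] + Rs[f - 1] @ local


def _point_jacobian(model: NeckModel, Rs, ps, axes, body: str,
                    pw: np.ndarray) -> np.ndarray:
    """3 x ndof Jacobian of a world point fixed to ``body``."""
    J = np.zeros((3, model.ndof))
    f = model.body_frame(body)
    for j in range(f):
        J[:, j] = np.cross(axes[j], pw - ps[j])
    return J


def forward_markers(model: NeckModel, q: np.ndarray) -> np.ndarray:
    """Positions of (TP, LH, RH) in the torso frame at pose ``q`` (3 x 3)."""
    Rs, ps, _ = _frames(model, q)
    return np.array([
        _point_world(model, Rs, ps, "head", model.marker_offsets[name])
        for name in MARKER_NAMES
    ])


def markers_for_motion(model: NeckModel, motion: MotionTrajectory) -> MarkerTrajectory:
    pos = np.array([forward_markers(model, qi) for qi in motion.q])
    return MarkerTrajectory(motion.times.copy(), pos)


def _muscle_endpoints(model: NeckModel, Rs, ps):
    orgs = np.array([_point_world(model, Rs, ps, m.origin_body, m.origin)
                     for m in model.muscles])
    inss = np.array([_point_world(model, Rs, ps, m.insertion_body, m.insertion)
                     for m in model.muscles])
    return orgs, inss


def muscle_lengths(model: NeckModel, q: np.ndarray) -> np.ndarray:
    Rs, ps, _ = _frames(model, q)
    orgs, inss = _muscle_endpoints(model, Rs, ps)
    return np.linalg.norm(inss - orgs, axis=1)


def moment_arm_matrix(model: NeckModel, q: np.ndarray) -> np.ndarray:
    """Moment arms (ndof x n_muscles); entry (j, i) = −∂l_i/∂q_j."""
    Rs, ps, axes = _frames(model, q)
    orgs, inss = _muscle_endpoints(model, Rs, ps)
    d = inss - orgs
    lengths = np.linalg.norm(d, axis=1)
    u = d / lengths[:, None]
    R = np.zeros((model.ndof, len(model.muscles)))
    for i, m in enumerate(model.muscles):
        Ji = _point_jacobian(model, Rs, ps, axes, m.insertion_body, inss[i])
        Jo = _point_jacobian(model, Rs, ps, axes, m.origin_body, orgs[i])
        R[:, i] = -(u[i] @ (Ji - Jo))
    return R


def muscle_length_rates(model: NeckModel, q: np.ndarray, qd: np.ndarray) -> np.ndarray:
    """dl/dt per muscle (m/s); equals −Rᵀ q̇ by the tendon-excursion relation."""
    return -(moment_arm_matrix(model, q).T @ np.asarray(qd, dtype=float))


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def _rnea(model: NeckModel, q, qd, qdd, with_gravity: bool = True) -> np.ndarray:
    """Generalized forces M q̈ + C q̇ + G via recursive Newton–Euler."""
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    qdd = np.asarray(qdd, dtype=float)
    Rs, ps, axes = _frames(model, q)
    g = np.array([0.0, 0.0, -model.gravity]) if with_gravity else np.zeros(3)

    # forward pass: frame spatial velocities/accelerations
    w = np.zeros(3); al = np.zeros(3)
    v = np.zeros(3); a = np.zeros(3)
    W, AL, A = [], [], []
    Rprev = np.eye(3)
    pprev = np.zeros(3)
    for j, joint in enumerate(model.joints):
        r = Rprev @ joint.offset
        v = v + np.cross(w, r)
        a = a + np.cross(al, r) + np.cross(w, np.cross(w, r))
        ax = axes[j]
        al = al + ax * qdd[j] + np.cross(w, ax) * qd[j]
        w = w + ax * qd[j]
        W.append(w.copy()); AL.append(al.copy()); A.append(a.copy())
        Rprev, pprev = Rs[j], ps[j]

    # body wrenches
    wrenches = []  # (frame, com_world, F, N)
    for b in model.bodies:
        f = b.frame
        Rb, pb = Rs[f - 1], ps[f - 1]
        cw = pb + Rb @ b.com
        r = cw - pb
        ac = A[f - 1] + np.cross(AL[f - 1], r) + np.cross(W[f - 1], np.cross(W[f - 1], r))
        Iw = Rb @ b.inertia @ Rb.T
        F = b.mass * (ac - g)
        N = Iw @ AL[f - 1] + np.cross(W[f - 1], Iw @ W[f - 1])
        wrenches.append((f, cw, F, N))

    tau = np.zeros(model.ndof)
    for j in range(model.ndof):
        for f, cw, F, N in wrenches:
            if f >= j + 1:
                tau[j] += axes[j] @ (N + np.cross(cw - ps[j], F))
    return tau


def inverse_dynamics(
    model: NeckModel,
    q: np.ndarray,
    qd: np.ndarray | None = None,
    qdd: np.ndarray | None = None,
    ext: ExternalLoad | None = None,
) -> np.ndarray:
    """Net joint moments the muscles must supply (N m).

    Returns τ = M(q) q̈ + C(q, q̇) q̇ + G(q) − τ_passive − Jᵀ F_ext, where
    the passive moment is the linear restoring term −K q − D q̇.
    """
    q = np.asarray(q, dtype=float)
    qd = np.zeros(model.ndof) if qd is None else np.asarray(qd, dtype=float)
    qdd = np.zeros(model.ndof) if qdd is None else np.asarray(qdd, dtype=float)
    tau = _rnea(model, q, qd, qdd)
    tau_passive = -model.passive_stiffness * q - model.passive_damping * qd
    tau = tau - tau_passive
    if ext is not None and (np.any(ext.force) or np.any(ext.moment)):
        Rs, ps, axes = _frames(model, q)
        body = next(b for b in model.bodies if b.name == ext.body)
        pw = _point_world(model, Rs, ps, ext.body, body.com)
        J = _point_jacobian(model, Rs, ps, axes, ext.body, pw)
        tau_ext = J.T @ ext.force
        f = model.body_frame(ext.body)
        for j in range(f):
            tau_ext[j] += axes[j] @ ext.moment
        tau = tau - tau_ext
    return tau


def mass_matrix(model: NeckModel, q: np.ndarray) -> np.ndarray:
    """Joint-space mass matrix via the unit-acceleration identity."""
    n = model.ndof
    base = _rnea(model, q, np.zeros(n), np.zeros(n), with_gravity=False)
    M = np.empty((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        M[:, k] = _rnea(model, q, np.zeros(n), e, with_gravity=False) - base
    return 0.5 * (M + M.T)


def mechanical_energy(model: NeckModel, q: np.ndarray, qd: np.ndarray) -> float:
    """Kinetic + gravitational potential energy of the chain (J)."""
    M = mass_matrix(model, q)
    ke = 0.5 * float(qd @ M @ qd)
    Rs, ps, _ = _frames(model, q)
    pe = 0.0
    for b in model.bodies:
        cw = _point_world(model, Rs, ps, b.name, b.com)
        pe += b.mass * model.gravity * cw[2]
    return ke + pe


def derive_kinematics(traj: MotionTrajectory) -> MotionTrajectory:
    """Attach q̇ and q̈ by finite differences (central interior, one-sided ends)."""
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    dt = float(traj.times[1] - traj.times[0])
    qd = np.gradient(traj.q, dt, axis=0)
    qdd = np.gradient(qd, dt, axis=0)
    return MotionTrajectory(traj.times.copy(), traj.q.copy(), traj.dof_names, qd, qdd)
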