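"""3-D motion envelopes, volumetric IoU, best-match search, deficit maps.

A marker's reachable region is bounded by an alpha shape of its 3-D
trajectory points; with the default alpha = ∞ this is the convex hull,
a faithful choice for the near-convex clouds produced by smooth head
motion.  Two envelopes are compared by volumetric intersection-over-union
evaluated on a shared axis-aligned voxel grid (deterministic and
resolution-controlled, unlike Monte-Carlo estimation).

A subject is matched against a database of simulated models by summing
the three per-marker IoUs (TP, LH, RH weighted equally) and taking the
model with the highest total.  Muscle-level deficits are then screened
by the ratio of peak muscle force predicted from the subject's actual
motion to that from the matched model's ideal motion: ratios well below
1 suggest underactivation of that muscle, ratios well above 1 suggest
compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay
from scipy.stats import ttest_rel

__all__ = [
    "Envelope",
    "AssessmentReport",
    "build_envelope",
    "envelope_iou",
    "best_match",
    "force_ratio_map",
    "paired_ttest",
    "envelope_to_mesh",
]


@dataclass
class Envelope:
    marker: str
    points: np.ndarray
    alpha: float
    volume: float
    _delaunay: Delaunay
    _kept: np.ndarray                  # mask over Delaunay simplices

    def contains(self, pts: np.ndarray) -> np.ndarray:
        simplex = self._delaunay.find_simplex(np.asarray(pts, dtype=float))
        inside = simplex >= 0
        if not np.all(self._kept):
            inside = inside & np.where(simplex >= 0, self._kept[simplex], False)
        return inside

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points.min(axis=0), self.points.max(axis=0)


def _tet_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    t = points[simplices]
    return np.abs(np.linalg.det(t[:, 1:] - t[:, :1])) / 6.0


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    radii = np.empty(len(simplices))
    for k, s in enumerate(simplices):
        p = points[s]
        A = 2.0 * (p[1:] - p[0])
        b = np.sum(p[1:] ** 2 - p[0] ** 2, axis=1)
        try:
            c = np.linalg.solve(A, b)
            radii[k] = np.linalg.norm(c - p[0])
        except np.linalg.LinAlgError:
            radii[k] = np.inf
    return radii


def build_envelope(points: np.ndarray, alpha: float = np.inf,
                   marker: str = "") -> Envelope:
    """Alpha-shape envelope of a 3-D point cloud.

    ``alpha = inf`` keeps every Delaunay tetrahedron, i.e. the convex
    hull; a finite alpha keeps only tetrahedra whose circumradius is at
    most ``alpha``.  Raises on fewer than 4 points or a coplanar cloud.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 4:
        raise ValueError("need at least 4 points in 3-D")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 3:
        raise ValueError("degenerate (coplanar or collinear) point set")
    tri = Delaunay(points)
    if np.isinf(alpha):
        kept = np.ones(len(tri.simplices), dtype=bool)
        volume = float(ConvexHull(points).volume)
    else:
        kept = _circumradii(points, tri.simplices) <= alpha
        if not kept.any():
            raise ValueError("alpha too small: empty alpha complex")
        volume = float(_tet_volumes(points, tri.simplices)[kept].sum())
    return Envelope(marker, points, float(alpha), volume, tri, kept)


def envelope_iou(A: Envelope, B: Envelope, resolution: int = 64) -> float:
    """Volumetric IoU of two envelopes on a shared voxel grid.

    The grid spans the joint bounding box at ``resolution`` cells per
    axis; containment is evaluated at cell centres.  Symmetric and
    deterministic for a fixed resolution.
    """
    lo = np.minimum(A.bounds[0], B.bounds[0])
    hi = np.maximum(A.bounds[1], B.bounds[1])
    axes = [np.linspace(lo[k], hi[k], resolution, endpoint=False)
            + (hi[k] - lo[k]) / (2 * resolution) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    in_a = A.contains(pts)
    in_b = B.contains(pts)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        raise ValueError("both envelopes are empty on the evaluation grid")
    return float(np.count_nonzero(in_a & in_b) / union)


@dataclass
class AssessmentReport:
    """Best-match outcome plus muscle-level deficit screen."""

    best_model: object
    per_marker_iou: dict[str, float]
    total_score: float
    all_scores: dict = field(default_factory=dict)
    force_ratios: pd.Series | None = None
    impaired: list[str] = field(default_factory=list)
    compensating: list[str] = field(default_factory=list)

    @property
    def average_iou(self) -> float:
        return float(np.mean(list(self.per_marker_iou.values())))

    def summary(self) -> str:
        lines = ["Subject\t" + "\t".join(f"{m} IoU" for m in self.per_marker_iou)
                 + "\tAverage IoU"]
        lines.append(
            "matched\t"
            + "\t".join(f"{v:.4f}" for v in self.per_marker_iou.values())
            + f"\t{self.average_iou:.4f}"
        )
        lines.append(f"best model: {self.best_model}  "
                     f"(total IoU score {self.total_score:.4f})")
        if self.impaired:
            lines.append("possible impairment (ratio low): " + ", ".join(self.impaired))
        if self.compensating:
            lines.append("possible compensation (ratio high): "
                         + ", ".join(self.compensating))
        return "\n".join(lines)


def best_match(
    subject_envelopes: dict[str, Envelope],
    database: dict[object, dict[str, Envelope]],
    resolution: int = 64,
) -> AssessmentReport:
    """Find the database model whose envelopes best cover the subject's.

    Each model's score is the sum of the three per-marker IoUs (equal
    importance); ties break toward the lowest model id.
    """
    if not database:
        raise ValueError("database must be nonempty")
    markers = list(subject_envelopes)
    scores: dict = {}
    per_marker: dict = {}
    for mid in sorted(database, key=str):
        envs = database[mid]
        missing = [m for m in markers if m not in envs]
        if missing:
            raise KeyError(f"model {mid!r} lacks envelope(s) for {missing}")
        ious = {m: envelope_iou(subject_envelopes[m], envs[m], resolution)
                for m in markers}
        scores[mid] = float(sum(ious.values()))
        per_marker[mid] = ious
    best = max(scores, key=lambda k: (scores[k], ))
    # deterministic tie-break: lowest id among maximal scores
    top = max(scores.values())
    best = sorted([k for k, v in scores.items() if v == top], key=str)[0]
    return AssessmentReport(best, per_marker[best], scores[best], all_scores=scores)


def force_ratio_map(
    actual: pd.DataFrame,
    ideal: pd.DataFrame,
    floor: float = 1e-6,
    theta_low: float = 0.85,
    theta_high: float = 1.15,
) -> tuple[pd.Series, list[str], list[str]]:
    """Per-muscle ratio of peak force, actual / ideal.

    Muscles whose ideal peak lies below ``floor`` are reported as NaN
    (undefined) rather than divided.  Returns the ratio series plus the
    muscles flagged as possibly impaired (ratio < theta_low) and
    possibly compensating (ratio > theta_high).
    """
    a = actual.drop(columns="time", errors="ignore")
    b = ideal.drop(columns="time", errors="ignore")
    if list(a.columns) != list(b.columns):
        raise ValueError("actual and ideal force tables list different muscles")
    peak_a = a.max(axis=0)
    peak_b = b.max(axis=0)
    ratios = pd.Series(
        np.where(peak_b > floor, peak_a / peak_b.where(peak_b > floor), np.nan),
        index=a.columns, name="force_ratio",
    )
    defined = ratios.dropna()
    impaired = list(defined[defined < theta_low].index)
    compensating = list(defined[defined > theta_high].index)
    return ratios, impaired, compensating


def paired_ttest(x, y) -> tuple[float, int, float]:
    """Paired two-sided t-test on matched samples; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    d = x - y
    if np.allclose(d, 0):
        return 0.0, x.size - 1, 1.0
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def envelope_to_mesh(env: Envelope):
    """Triangle mesh of the envelope surface (a trimesh.Trimesh)."""
    import trimesh

    if np.all(env._kept):
        hull = ConvexHull(env.points)
        mesh = trimesh.Trimesh(vertices=env.points, faces=hull.simplices)
    else:
        # boundary faces: triangles belonging to exactly one kept tetrahedron
        from collections import Counter

        faces = Counter()
        for s, keep in zip(env._delaunay.simplices, env._kept):
            if not keep:
                continue
            for drop in range(4):
                face = tuple(sorted(np.delete(s, drop)))
                faces[face] += 1
        boundary = [f for f, c in faces.items() if c == 1]
        mesh = trimesh.Trimesh(vertices=env.points, faces=np.array(boundary))
    mesh.fix_normals()
    return mesh
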