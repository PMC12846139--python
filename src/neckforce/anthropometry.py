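"""Anthropometric population statistics and model personalization.

The head–neck model is personalized by three parameters that dominate
cervical muscle loading: head mass (gravitational demand), biacromial
shoulder width (lateral muscle attachment geometry) and neck length
(gravitational lever arm and muscle paths).  Population statistics for
the three parameters — a mean vector and full covariance matrix derived
from a large military anthropometric survey — ship with the package, so
plausible virtual subjects can be drawn from a multivariate normal
distribution without any external data.

Units at this interface are kg and cm; the rigid-body model works in SI
(kg, m) and :func:`scale_model` is the only place the conversion happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PopulationStats",
    "AnthroProfile",
    "DEFAULT_POPULATION",
    "sample_population",
    "head_mass_from_body_weight",
    "profiles_to_frame",
    "profiles_from_frame",
]

#: Packaged population statistics: mean and covariance of
#: (head mass kg, biacromial breadth cm, neck length cm).
_DEFAULT_MEAN = np.array([6.377, 39.920, 10.730])
_DEFAULT_COV = np.array(
    [
        [1.568, 2.678, -0.001],
        [2.678, 9.143, 0.378],
        [-0.001, 0.378, 1.546],
    ]
)


@dataclass(frozen=True)
class PopulationStats:
    """Multivariate-normal parameters of the three personalization traits.

    Component order is (head mass kg, shoulder width cm, neck length cm).
    """

    mean: np.ndarray = field(default_factory=lambda: _DEFAULT_MEAN.copy())
    covariance: np.ndarray = field(default_factory=lambda: _DEFAULT_COV.copy())

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.shape != (3,):
            raise ValueError("mean must be a 3-vector")
        if cov.shape != (3, 3):
            raise ValueError("covariance must be 3x3")
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ValueError("covariance must be positive semidefinite")
        if np.any(mean <= 0):
            raise ValueError("mean components must be strictly positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)


@dataclass(frozen=True)
class AnthroProfile:
    """A single virtual subject's personalization parameters."""

    head_mass: float  # kg
    shoulder_width: float  # cm
    neck_length: float  # cm

    def __post_init__(self) -> None:
        if min(self.head_mass, self.shoulder_width, self.neck_length) <= 0:
            raise ValueError("all anthropometric parameters must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.head_mass, self.shoulder_width, self.neck_length])


DEFAULT_POPULATION = PopulationStats()


def head_mass_from_body_weight(body_weight: float) -> float:
    """Estimate head mass as 8% of total body weight (kg)."""
    if body_weight <= 0:
        raise ValueError("body weight must be strictly positive")
    return 0.08 * body_weight


def sample_population(
    stats: PopulationStats, n: int, seed: int | None = None
) -> list[AnthroProfile]:
    """Draw ``n`` anatomically plausible profiles from the population.

    Draws come from the multivariate normal defined by ``stats``.  Draws
    with any nonpositive component, or any component further than 5
    standard deviations from its mean, are rejected and redrawn — a
    negligible-probability guard that keeps every returned profile
    anatomically plausible.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    stats = stats if isinstance(stats, PopulationStats) else PopulationStats(*stats)
    rng = np.random.default_rng(seed)
    sd = np.sqrt(np.diag(stats.covariance))
    lo = np.maximum(stats.mean - 5.0 * sd, 0.0)
    hi = stats.mean + 5.0 * sd
    out = np.empty((0, 3))
    while out.shape[0] < n:
        block = rng.multivariate_normal(
            stats.mean, stats.covariance, size=max(n - out.shape[0], 1), method="svd"
        )
        # inclusive window so degenerate (zero-variance) dimensions, whose
        # draws sit exactly at the mean, are not rejected forever
        ok = np.all((block >= lo) & (block <= hi) & (block > 0), axis=1)
        out = np.vstack([out, block[ok]])
    out = out[:n]
    return [AnthroProfile(*row) for row in out]


def profiles_to_frame(profiles: list[AnthroProfile], seed: int | None = None) -> pd.DataFrame:
    """Tabulate sampled profiles (CSV-ready, one row per virtual subject)."""
    return pd.DataFrame(
        {
            "id": np.arange(len(profiles)),
            "head_mass_kg": [p.head_mass for p in profiles],
            "shoulder_width_cm": [p.shoulder_width for p in profiles],
            "neck_length_cm": [p.neck_length for p in profiles],
            "seed": seed if seed is not None else pd.NA,
        }
    )


def scale_model(base, profile: AnthroProfile):
    """Scale a neck model to a profile (convenience re-export)."""
    from .model import scale_model as _scale

    return _scale(base, profile)


def profiles_from_frame(frame: pd.DataFrame) -> list[AnthroProfile]:
    return [
        AnthroProfile(r.head_mass_kg, r.shoulder_width_cm, r.neck_length_cm)
        for r in frame.itertuples()
    ]
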