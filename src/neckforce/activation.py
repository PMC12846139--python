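"""Hill-type activation inversion and sEMG envelope processing.

Predicted muscle forces are mapped back to unitless activations through
the Hill-type relation

    a(t) = F(t) / (F_max · f_length(l̃) · f_velocity(ṽ)),

where l̃ is fiber length normalized by optimal length and ṽ shortening
velocity normalized by maximal shortening velocity.  The force–length
multiplier defaults to a Gaussian about the optimum, f_l = exp(−((l̃−1)/w)²)
with width w = 0.45; the force–velocity multiplier is the classic Hill
hyperbola on the concentric side with an eccentric plateau of 1.4.  The
quotient can exceed 1 when predicted force outruns the multipliers, so
activations are clipped to [0, 1] and the clip rate is reported rather
than silently saturated.

Surface EMG channels are reduced to linear envelopes by the standard
chain: 20–450 Hz fourth-order Butterworth band-pass, full-wave
rectification, 10 Hz low-pass, normalization by maximal voluntary
contraction (MVC), and resampling to the 100 Hz marker timebase.  All
filtering is zero-phase (forward–backward), which doubles the effective
order but avoids phase lag when correlating envelopes with predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import pearsonr

__all__ = [
    "HillParams",
    "EMGRecording",
    "force_length",
    "force_velocity",
    "activation_from_force",
    "process_semg",
    "pearson",
    "normalized_fiber_state",
]


@dataclass(frozen=True)
class HillParams:
    f_max: float                    # N
    optimal_fiber_length: float     # m
    max_shortening_velocity: float = 10.0   # optimal lengths / s
    fl_width: float = 0.45          # Gaussian force-length width
    fv_shape: float = 0.25          # Hill hyperbola curvature parameter
    eccentric_plateau: float = 1.4

    def __post_init__(self) -> None:
        if min(self.f_max, self.optimal_fiber_length, self.max_shortening_velocity,
               self.fl_width, self.fv_shape, self.eccentric_plateau) <= 0:
            raise ValueError("all Hill parameters must be positive")


@dataclass(frozen=True)
class EMGRecording:
    channel: str
    samples: np.ndarray             # mV
    fs: float = 1000.0              # Hz
    mvc: float = 1.0                # MVC reference amplitude, mV

    def __post_init__(self) -> None:
        if self.mvc <= 0:
            raise ValueError("MVC must be positive")
        if self.fs <= 2 * 450.0:
            raise ValueError("sampling rate must exceed twice the band upper edge")


def force_length(l_norm, width: float = 0.45):
    """Gaussian force–length multiplier; 1 at the optimal length."""
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise ValueError("normalized length must be positive")
    out = np.exp(-(((l_norm - 1.0) / width) ** 2))
    return float(out) if out.ndim == 0 else out


def force_velocity(v_norm, shape: float = 0.25, eccentric_plateau: float = 1.4):
    """Hill force–velocity multiplier; 1 isometric, 0 at max shortening.

    ``v_norm`` is positive for shortening (concentric), negative for
    lengthening; lengthening rises smoothly toward the eccentric plateau.
    """
    v = np.atleast_1d(np.asarray(v_norm, dtype=float))
    out = np.empty_like(v)
    con = v >= 0
    vc = np.clip(v[con], 0.0, 1.0)
    out[con] = (1.0 - vc) / (1.0 + vc / shape)
    ve = -v[~con]
    p = eccentric_plateau
    out[~con] = p - (p - 1.0) / (1.0 + ve / shape)
    return float(out[0]) if np.isscalar(v_norm) or np.ndim(v_norm) == 0 else out


def activation_from_force(F, hill: HillParams, l_norm=1.0, v_norm=0.0):
    """Invert the Hill relation: a = F / (F_max f_l f_v), clipped to [0, 1].

    Returns ``(a, clip_rate)`` where ``clip_rate`` is the fraction of
    samples whose raw quotient exceeded 1.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be nonnegative")
    fl = force_length(l_norm, hill.fl_width)
    fv = force_velocity(v_norm, hill.fv_shape, hill.eccentric_plateau)
    denom = hill.f_max * fl * fv
    if np.any(np.asarray(denom) == 0):
        raise ZeroDivisionError("force-length/velocity multipliers vanish")
    raw = F / denom
    clip_rate = float(np.mean(np.asarray(raw) > 1.0))
    a = np.clip(raw, 0.0, 1.0)
    return (float(a), clip_rate) if a.ndim == 0 else (a, clip_rate)


def normalized_fiber_state(length, rest_length, length_rate,
                           max_shortening_velocity: float = 10.0):
    """Straight-line analog of fiber state: l̃ = l/l₀, ṽ = −l̇/(l₀ v_max)."""
    l_norm = np.asarray(length, dtype=float) / rest_length
    v_norm = -np.asarray(length_rate, dtype=float) / (
        rest_length * max_shortening_velocity
    )
    return l_norm, v_norm


def process_semg(rec: EMGRecording, out_fs: float = 100.0) -> np.ndarray:
    """Linear envelope of an sEMG channel on the marker timebase.

    Band-pass (20–450 Hz, 4th-order Butterworth) → full-wave rectify →
    low-pass (10 Hz) → divide by MVC → resample to ``out_fs``.  Filters
    run zero-phase.
    """
    x = np.asarray(rec.samples, dtype=float)
    if x.size < 12 * int(rec.fs / 100):     # filtfilt padding requirement
        raise ValueError("signal too short for filter warm-up")
    sos_bp = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos_bp, x)
    x = np.abs(x)
    sos_lp = sps.butter(4, 10.0, btype="lowpass", fs=rec.fs, output="sos")
    env = sps.sosfiltfilt(sos_lp, x) / rec.mvc
    decim = int(round(rec.fs / out_fs))
    if abs(rec.fs / out_fs - decim) < 1e-9 and decim >= 1:
        return env[::decim]
    t_in = np.arange(x.size) / rec.fs
    t_out = np.arange(0, t_in[-1] + 0.5 / out_fs, 1.0 / out_fs)
    return np.interp(t_out, t_in, env)


def pearson(a, b) -> float:
    """Product-moment correlation between two equal-length series."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("inputs must be equal-length with >= 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(pearsonr(a, b).statistic)
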