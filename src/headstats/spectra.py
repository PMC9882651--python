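"""Gravitational/inertial acceleration decomposition and power spectra.

The sensed (total) linear acceleration at the head is the sum of a
gravitational component - the world gravity vector expressed in the head
frame - and an inertial component driven by self-motion.  Given the
orientation stream the two are separated exactly:

    a_grav(t) = R(q_world_head(t)) @ g_world,   a_inert = a_total - a_grav.

Per-axis power spectral densities are Welch estimates (Hann window, 50%
overlap, per-segment mean removal) computed independently over each
contiguous run of retained samples - gaps from the exclusion mask are
never concatenated, which would fabricate discontinuity power.  The
crossing point per axis is the frequency at which inertial power first
exceeds gravitational power and stays above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import MotionRecording
from .rotations import GRAVITY_WORLD, quat_norm_error, rotation_from_quats

AXES = ("x", "y", "z")


@dataclass
class AccelDecomposition:
    """Head-frame gravitational and inertial acceleration series (m/s^2).

    Axis labels: X nasal-occipital, Y interaural, Z dorsal-ventral.
    a_grav + a_inert reproduces the total acceleration to float round-off
    and |a_grav| equals 9.81 m/s^2 at every sample.
    """

    a_grav: np.ndarray
    a_inert: np.ndarray
    a_total: np.ndarray


@dataclass
class CrossingPoint:
    axis: str
    f_cross: float
    found: bool


@dataclass
class SpectraSet:
    """Per-axis PSDs of gravitational, inertial, and total acceleration."""

    freqs: np.ndarray
    P_grav: np.ndarray   # (n_freq, 3)
    P_inert: np.ndarray
    P_total: np.ndarray
    fs: float
    nfft: int
    crossings: list[CrossingPoint] = field(default_factory=list)
    n_segments_used: int = 0
    n_segments_skipped: int = 0


def decompose_acceleration(rec: MotionRecording,
                           g_world: np.ndarray = GRAVITY_WORLD) -> AccelDecomposition:
    """Split total sensed acceleration into gravitational and inertial parts."""
    if np.any(quat_norm_error(rec.q_world_head) > 1e-3):
        raise ValueError("non-unit quaternions; recording not valid")
    rot = rotation_from_quats(rec.q_world_head)
    a_grav = rot.apply(np.asarray(g_world, float))
    a_inert = rec.a_total_sensor - a_grav
    return AccelDecomposition(a_grav=a_grav, a_inert=a_inert,
                              a_total=rec.a_total_sensor)


def _retained_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    m = np.asarray(mask, bool)
    if m.ndim != 1:
        raise ValueError("mask must be 1-D")
    padded = np.r_[False, m, False].astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return [(int(s), int(e)) for s, e in zip(starts, stops)]


def power_spectrum(x: np.ndarray, fs: float = 62.5, nfft: int = 512,
                   mask: np.ndarray | None = None):
    """Welch PSD over contiguous retained runs of a (possibly 3-axis) signal.

    Runs shorter than ``nfft`` are skipped (counted); the remaining
    per-run Welch estimates (Hann, 50% overlap, constant detrend) are
    averaged with weights equal to their number of windowed sub-segments.
    Density normalization: a unit-amplitude sinusoid at a bin centre
    integrates to A^2/2.

    Returns ``(freqs, psd, n_used, n_skipped)`` with ``psd`` shaped
    (n_freq,) for 1-D input or (n_freq, n_axes) otherwise.
    """
    x = np.asarray(x, float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n = len(x)
    if mask is None:
        mask = np.ones(n, bool)
    runs = _retained_runs(np.asarray(mask, bool))
    step = nfft - nfft // 2
    acc = None
    weight = 0.0
    n_used = n_skipped = 0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    for s, e in runs:
        if e - s < nfft:
            n_skipped += 1
            continue
        f, p = signal.welch(x[s:e], fs=fs, window="hann", nperseg=nfft,
                            noverlap=nfft // 2, detrend="constant", axis=0)
        w = (e - s - nfft // 2) // step
        acc = p * w if acc is None else acc + p * w
        weight += w
        n_used += 1
    if acc is None:
        raise ValueError(f"no contiguous retained run of length >= {nfft}")
    psd = acc / weight
    if one_d:
        psd = psd[:, 0]
    return freqs, psd, n_used, n_skipped


def find_crossing(P_grav: np.ndarray, P_inert: np.ndarray, freqs: np.ndarray,
                  axis: str = "", persistence: int = 3,
                  smooth_bins: int = 3) -> CrossingPoint:
    """Lowest frequency where inertial power durably exceeds gravitational.

    Both spectra are log10-transformed and smoothed with a
    ``smooth_bins``-bin moving average (DC bin excluded).  The crossing is
    the first negative-to-positive sign change of log P_inert - log P_grav
    that stays positive for at least ``persistence`` bins, refined by
    linear interpolation of the log-power difference between the
    bracketing bins.  ``found=False`` is a valid no-crossing result.
    """
    f = np.asarray(freqs, float)
    keep = f > 0
    f = f[keep]
    with np.errstate(divide="ignore"):
        lg = np.log10(np.maximum(np.asarray(P_grav, float)[keep], 1e-300))
        li = np.log10(np.maximum(np.asarray(P_inert, float)[keep], 1e-300))
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        # edge-preserving "same" smoothing via normalized convolution
        ones = np.convolve(np.ones_like(lg), kernel, mode="same")
        lg = np.convolve(lg, kernel, mode="same") / ones
        li = np.convolve(li, kernel, mode="same") / ones
    d = li - lg
    for i in range(1, len(d)):
        if d[i - 1] < 0 <= d[i] and np.all(d[i:i + persistence] > 0) \
                and i + persistence <= len(d):
            frac = -d[i - 1] / (d[i] - d[i - 1])
            f_cross = f[i - 1] + frac * (f[i] - f[i - 1])
            return CrossingPoint(axis=axis, f_cross=float(f_cross), found=True)
    return CrossingPoint(axis=axis, f_cross=float("nan"), found=False)


def compute_spectra(rec: MotionRecording, mask: np.ndarray | None = None,
                    fs: float | None = None, nfft: int = 512,
                    g_world: np.ndarray = GRAVITY_WORLD) -> SpectraSet:
    """Decompose an aligned recording and compute per-axis PSDs + crossings."""
    fs = rec.sample_rate if fs is None else fs
    dec = decompose_acceleration(rec, g_world=g_world)
    freqs, pg, used, skipped = power_spectrum(dec.a_grav, fs, nfft, mask)
    _, pi, _, _ = power_spectrum(dec.a_inert, fs, nfft, mask)
    _, pt, _, _ = power_spectrum(dec.a_total, fs, nfft, mask)
    crossings = [find_crossing(pg[:, k], pi[:, k], freqs, axis=AXES[k])
                 for k in range(3)]
    return SpectraSet(freqs=freqs, P_grav=pg, P_inert=pi, P_total=pt, fs=fs,
                      nfft=nfft, crossings=crossings,
                      n_segments_used=used, n_segments_skipped=skipped)
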