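"""Head orientation angles, distributional summaries, and KDE priors.

Quaternions are converted to intrinsic yaw-pitch-roll (Z-Y'-X'') angles
under the package convention (positive pitch up, positive roll
left-ear-down).  The descriptive statistics follow the population-moment
(Fisher) definitions of skewness and excess kurtosis, i.e. the behaviour
of ``scipy.stats.describe``; the kernel density estimates are plain
Gaussian kernel sums on a whole-degree grid, renormalized to integrate to
one over their stated range so they can double as Bayesian priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rotations import angles_from_attitude, quat_norm_error, rotation_from_quats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AngleSeries:
    """Per-sample head Euler angles in degrees."""

    t: np.ndarray | None
    pitch: np.ndarray
    roll: np.ndarray
    yaw: np.ndarray
    velocity_class: np.ndarray | None = None
    gimbal_flag: np.ndarray | None = None


@dataclass
class MomentSummary:
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    n: int

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "skewness": self.skewness,
                "excess_kurtosis": self.excess_kurtosis, "n": self.n}


@dataclass
class AsymmetrySummary:
    """One-sided variability about the KDE mode.

    ``var_below``/``var_above`` are RMS deviations of the samples strictly
    below/above the mode.  ``ratio`` is larger / smaller (always >= 1) and
    ``heavier_side`` says which side it refers to.  For pitch under the
    package sign convention, "below" is forward/downward pitch.
    """

    mode: float
    var_below: float
    var_above: float
    ratio: float
    heavier_side: str  # "below" | "above"
    unimodal: bool = True

    def as_dict(self) -> dict:
        return {"mode": self.mode, "var_below": self.var_below,
                "var_above": self.var_above, "ratio": self.ratio,
                "heavier_side": self.heavier_side, "unimodal": self.unimodal}


@dataclass
class EmpiricalPrior:
    """Normalized density on a uniformly spaced angle grid (degrees)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    range: tuple[float, float]
    n_clipped: int = 0

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def normalize(self) -> "EmpiricalPrior":
        total = float(np.sum(self.density) * self.step)
        if total <= 0:
            raise ValueError("density has no mass on the grid")
        self.density = self.density / total
        return self

    def mean(self) -> float:
        return float(np.sum(self.grid * self.density) * self.step)

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])

    @classmethod
    def from_density(cls, grid: np.ndarray, density: np.ndarray,
                     bandwidth: float = float("nan")) -> "EmpiricalPrior":
        grid = np.asarray(grid, float)
        density = np.asarray(density, float)
        if np.any(density < 0):
            raise ValueError("density must be non-negative")
        prior = cls(grid=grid, density=density.copy(), bandwidth=bandwidth,
                    range=(float(grid[0]), float(grid[-1])))
        return prior.normalize()

    @classmethod
    def uniform(cls, lo: float, hi: float, step: float = 1.0) -> "EmpiricalPrior":
        grid = np.arange(lo, hi + step / 2, step)
        return cls.from_density(grid, np.ones_like(grid))

    def to_csv(self, path) -> None:
        import pandas as pd
        with open(path, "w") as fh:
            fh.write(f"# bandwidth_deg={self.bandwidth}, n_clipped={self.n_clipped}\n")
            pd.DataFrame({"angle_deg": self.grid,
                          "density_per_deg": self.density}).to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "EmpiricalPrior":
        import pandas as pd
        df = pd.read_csv(path, comment="#")
        return cls.from_density(df["angle_deg"].to_numpy(float),
                                df["density_per_deg"].to_numpy(float))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def quaternion_to_angles(q: np.ndarray, t: np.ndarray | None = None,
                         velocity_class: np.ndarray | None = None,
                         gimbal_margin_deg: float = 89.9) -> AngleSeries:
    """Euler angles (degrees) from world->head quaternions.

    Samples with |pitch| beyond ``gimbal_margin_deg`` are flagged as
    gimbal-adjacent (yaw/roll become poorly conditioned there).
    """
    q = np.atleast_2d(np.asarray(q, float))
    err = quat_norm_error(q)
    if np.any(err > 1e-3):
        raise ValueError(f"non-unit quaternion (max norm error {err.max():.2e})")
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    attitude = rotation_from_quats(q).inv()
    yaw, pitch, roll = angles_from_attitude(attitude)
    return AngleSeries(
        t=t, pitch=pitch, roll=roll, yaw=yaw,
        velocity_class=velocity_class,
        gimbal_flag=np.abs(pitch) > gimbal_margin_deg,
    )


def compute_moments(samples) -> MomentSummary:
    """Mean, SD (n-1), and population-definition skewness/excess kurtosis."""
    x = np.asarray(samples, float)
    if x.ndim != 1:
        x = x.ravel()
    if len(x) < 4:
        raise ValueError("need at least 4 samples for kurtosis")
    return MomentSummary(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        skewness=float(stats.skew(x, bias=True)),
        excess_kurtosis=float(stats.kurtosis(x, fisher=True, bias=True)),
        n=len(x),
    )


def scott_bandwidth(samples: np.ndarray) -> float:
    """Scott's rule: sd * n^(-1/5) (1-D Gaussian kernels)."""
    x = np.asarray(samples, float)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("all samples identical: zero bandwidth")
    return sd * len(x) ** (-0.2)


def _kde_on_grid(x: np.ndarray, grid: np.ndarray, bandwidth: float,
                 chunk: int = 64) -> np.ndarray:
    """Plain Gaussian kernel-sum density, evaluated exactly (chunked)."""
    out = np.empty(len(grid))
    norm = 1.0 / (len(x) * bandwidth * np.sqrt(2.0 * np.pi))
    for i in range(0, len(grid), chunk):
        g = grid[i:i + chunk, None]
        out[i:i + chunk] = np.exp(-0.5 * ((g - x[None, :]) / bandwidth) ** 2).sum(axis=1)
    return out * norm


def estimate_kde(samples, angle_range: tuple[float, float],
                 grid_step: float = 1.0,
                 bandwidth: float | None = None) -> EmpiricalPrior:
    """Gaussian-kernel density on a uniform grid, normalized over the range.

    Samples outside the range are clipped out of the estimate (their count
    is logged and recorded on the returned prior).  Bandwidth defaults to
    Scott's rule on the retained sample.
    """
    x = np.asarray(samples, float).ravel()
    if len(x) < 100:
        raise ValueError("need at least 100 samples for a KDE prior")
    lo, hi = float(angle_range[0]), float(angle_range[1])
    keep = (x >= lo) & (x <= hi)
    n_clipped = int(len(x) - keep.sum())
    if n_clipped:
        logger.info("estimate_kde: clipped %d samples outside [%g, %g]",
                    n_clipped, lo, hi)
    x = x[keep]
    if len(x) < 100:
        raise ValueError("fewer than 100 samples inside the KDE range")
    if bandwidth is None:
        bandwidth = scott_bandwidth(x)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    density = _kde_on_grid(x, grid, bandwidth)
    prior = EmpiricalPrior(grid=grid, density=density, bandwidth=float(bandwidth),
                           range=(lo, hi), n_clipped=n_clipped)
    return prior.normalize()


def asymmetry_ratio(samples, bandwidth: float | None = None,
                    mode_bandwidth_scale: float = 3.0,
                    refine_step: float = 0.02) -> AsymmetrySummary:
    """One-sided RMS variability about the KDE mode.

    The mode is the argmax of a Gaussian KDE (coarse pass at 0.25 deg,
    refined at ``refine_step``) whose bandwidth is ``mode_bandwidth_scale``
    times Scott's rule - a pilot oversmoothing that keeps the peak
    location stable against sampling noise.  Variability on each side is
    the RMS deviation of the samples strictly below/above the mode; the
    reported ratio is larger/smaller with a flag for which side is
    heavier.  A multimodal KDE is logged and flagged, not rejected.
    """
    x = np.asarray(samples, float).ravel()
    if len(x) < 100:
        raise ValueError("need at least 100 samples")
    if bandwidth is None:
        bandwidth = scott_bandwidth(x) * mode_bandwidth_scale
    lo, hi = x.min() - bandwidth, x.max() + bandwidth
    coarse_step = min(0.25, (hi - lo) / 200.0)
    coarse = np.arange(lo, hi + coarse_step / 2, coarse_step)
    dens = _kde_on_grid(x, coarse, bandwidth)
    peak = int(np.argmax(dens))
    interior = dens[1:-1]
    n_local_max = int(np.sum((interior > dens[:-2]) & (interior > dens[2:])
                             & (interior > 0.05 * dens[peak])))
    unimodal = n_local_max <= 1
    if not unimodal:
        logger.warning("asymmetry_ratio: KDE has %d local maxima", n_local_max)
    f_lo = coarse[max(peak - 8, 0)]
    f_hi = coarse[min(peak + 8, len(coarse) - 1)]
    fine = np.arange(f_lo, f_hi + refine_step / 2, min(refine_step, coarse_step))
    mode = float(fine[np.argmax(_kde_on_grid(x, fine, bandwidth))])
    mode = round(mode, 9)  # strip grid-accumulation float noise
    below = x[x < mode]
    above = x[x > mode]
    if len(below) == 0 or len(above) == 0:
        raise ValueError("no samples on one side of the mode")
    rms_below = float(np.sqrt(np.mean((below - mode) ** 2)))
    rms_above = float(np.sqrt(np.mean((above - mode) ** 2)))
    if rms_below >= rms_above:
        ratio, side = rms_below / rms_above, "below"
    else:
        ratio, side = rms_above / rms_below, "above"
    return AsymmetrySummary(mode=mode, var_below=rms_below, var_above=rms_above,
                            ratio=float(ratio), heavier_side=side,
                            unimodal=unimodal)
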