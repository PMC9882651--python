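"""End-to-end orchestration: simulate/load -> calibrate -> preprocess ->
orientation statistics -> gravitoinertial spectra -> psychophysical fits.

A run is driven by a single :class:`RunConfig` (optionally read from
YAML), writes every intermediate artifact plus a machine-readable
manifest (content hashes, configuration echo, library versions, seed),
and is exactly reproducible for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import apply_recalibrations, windows_from_recording
from .orientation import (asymmetry_ratio, compute_moments, estimate_kde,
                          quaternion_to_angles)
from .perception import (DEFAULT_ADDITIVE_SD, PsychBiasTable, fit_sigma)
from .preprocess import (CONFIDENCE_MIN, SPEED_EXCLUDE_MPS,
                         VELOCITY_SPLIT_MPS, build_mask, retention_summary)
from .recording import MotionRecording
from .spectra import compute_spectra
from .synthetic import SimConfig, simulate_recording

logger = logging.getLogger(__name__)

_SIM_SCALAR_KEYS = ("seed", "duration_s", "sample_rate",
                    "orientation_relaxation_time_s",
                    "orientation_smoothing_time_s",
                    "stationary_fraction_target", "misalignment_deg")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Thresholds and model ranges default to the analysis constants
    (3.05 m/s exclusion, 0.75 m/s low/high split, confidence 3,
    fs 62.5 Hz / nfft 512, roll prior +/-120 deg, pitch prior +/-90 deg).
    """

    seed: int = 0
    recording_path: str | None = None
    duration_s: float = 21600.0
    simulation: dict = field(default_factory=dict)
    manual_exclude: list = field(default_factory=list)
    speed_exclude_mps: float = SPEED_EXCLUDE_MPS
    velocity_split_mps: float = VELOCITY_SPLIT_MPS
    confidence_min: int = CONFIDENCE_MIN
    nfft: int = 512
    pitch_range_deg: float = 90.0
    roll_range_deg: float = 120.0
    additive_sd_deg: float = DEFAULT_ADDITIVE_SD
    noise_kinds: tuple = ("linear", "shear")
    sigma_bounds: tuple = (0.0, 1.0)
    psych_roll_path: str | None = None
    psych_pitch_path: str | None = None
    write_recording: bool = False

    def __post_init__(self):
        if min(self.speed_exclude_mps, self.velocity_split_mps, self.nfft) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        overrides = dict(self.simulation)
        cfg = SimConfig(seed=self.seed, duration_s=self.duration_s)
        for key, value in overrides.items():
            if key not in _SIM_SCALAR_KEYS:
                raise ValueError(f"unsupported simulation override: {key}")
            setattr(cfg, key, value)
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_kinds"] = list(self.noise_kinds)
        d["sigma_bounds"] = list(self.sigma_bounds)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages, write artifacts to ``outdir``, return the summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # 1. input ------------------------------------------------------------
    stage("input")
    if config.recording_path:
        rec = MotionRecording.read_csv(config.recording_path)
    else:
        rec = simulate_recording(config.sim_config())
        if config.write_recording:
            rec.write_csv(out / "recording.csv",
                          sidecar=dataclasses.asdict(config.sim_config()))
    rec.validate()

    # 2. calibration ------------------------------------------------------
    stage("calibration")
    windows = windows_from_recording(rec)
    if not windows:
        raise RuntimeError("stage calibration: no calibration blocks found")
    aligned, alignments = apply_recalibrations(rec, windows)
    _dump({
        "n_blocks": len(windows),
        "alignments": [{
            "R_sensor_head": a.R_sensor_head.tolist(),
            "axis_residual_deg": a.axis_residual_deg,
            "reid_pitch_offset_deg": a.reid_pitch_offset_deg,
        } for a in alignments],
    }, out / "alignment.json")

    # 3. preprocessing ----------------------------------------------------
    stage("preprocess")
    mask = build_mask(aligned, windows=None,
                      manual_intervals=config.manual_exclude or None,
                      speed_threshold=config.speed_exclude_mps,
                      confidence_min=config.confidence_min,
                      velocity_split=config.velocity_split_mps)
    retention = retention_summary(mask, rec.sample_rate)
    _dump(retention, out / "retention.json")
    summary["retention"] = retention

    # 4. orientation statistics -------------------------------------------
    stage("orientation statistics")
    angles = quaternion_to_angles(aligned.q_world_head, t=aligned.t)
    classes = {"all": mask.retained, "low": mask.low, "high": mask.high}
    moments = {}
    priors = {}
    for cls_name, sel in classes.items():
        if sel.sum() < 100:
            logger.warning("skipping class %s: too few samples", cls_name)
            continue
        moments[cls_name] = {
            "pitch": compute_moments(angles.pitch[sel]).as_dict(),
            "roll": compute_moments(angles.roll[sel]).as_dict(),
        }
        priors[("pitch", cls_name)] = estimate_kde(
            angles.pitch[sel], (-config.pitch_range_deg, config.pitch_range_deg))
        priors[("roll", cls_name)] = estimate_kde(
            angles.roll[sel], (-config.roll_range_deg, config.roll_range_deg))
    for (which, cls_name), prior in priors.items():
        prior.to_csv(out / f"prior_{which}_{cls_name}.csv")
    asym = asymmetry_ratio(angles.pitch[mask.retained])
    _dump({"moments": moments, "pitch_asymmetry": asym.as_dict()},
          out / "moments.json")
    summary["moments"] = moments
    summary["pitch_asymmetry"] = asym.as_dict()

    # 5. spectra -----------------------------------------------------------
    stage("spectra")
    crossings = {}
    for cls_name, sel in classes.items():
        try:
            ss = compute_spectra(aligned, mask=sel, nfft=config.nfft)
        except ValueError as exc:
            logger.warning("spectra for class %s skipped: %s", cls_name, exc)
            continue
        frame = {"freq_hz": ss.freqs}
        for k, axis in enumerate("xyz"):
            frame[f"P_grav_{axis}"] = ss.P_grav[:, k]
            frame[f"P_inert_{axis}"] = ss.P_inert[:, k]
            frame[f"P_total_{axis}"] = ss.P_total[:, k]
        pd.DataFrame(frame).to_csv(out / f"spectra_{cls_name}.csv", index=False,
                                   float_format="%.8g")
        crossings[cls_name] = [{"axis": c.axis, "f_cross_hz": c.f_cross,
                                "found": c.found} for c in ss.crossings]
        if cls_name == "high":
            pz = ss.P_inert[1:, 2]
            summary["z_peak_high_hz"] = float(ss.freqs[1:][int(np.argmax(pz))])
    _dump(crossings, out / "crossings.json")
    summary["crossings"] = crossings

    # 6. psychophysical fits ----------------------------------------------
    stage("perception fits")
    fits = {}
    tables = {"roll": config.psych_roll_path, "pitch": config.psych_pitch_path}
    for which, path in tables.items():
        if not path:
            logger.info("no %s psychophysical table supplied; fit skipped", which)
            continue
        observed = PsychBiasTable.read_csv(path)
        prior = priors[(which, "all")]
        for kind in config.noise_kinds:
            fit = fit_sigma(prior, observed, kind,
                            additive_sd=config.additive_sd_deg,
                            bounds=tuple(config.sigma_bounds))
            fits[f"{which}_{kind}"] = fit.as_dict()
    if fits:
        _dump(fits, out / "fits.json")
    summary["fits"] = fits

    # 7. summary + manifest -------------------------------------------------
    _dump(summary, out / "summary.json")
    import scipy
    manifest = {
        "config": config.as_dict(),
        "seed": config.seed,
        "versions": {"headstats": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "outputs": {},
    }
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or not path.is_file():
            continue
        manifest["outputs"][path.name] = _sha256(path)
    _dump(manifest, out / "manifest.json")
    return summary
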