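"""Synthetic postural-sway cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, without claiming physiological detail:

* COP sway per condition is an independent pair (ML, AP) of discretised
  mean-reverting Gaussian random walks (a discrete Ornstein-Uhlenbeck
  process), whose noise amplitude ``sway_scale`` sets the average COP
  velocity. Per-condition scales are calibrated so the simulated mean AV
  matches the study-condition targets (EOSS 0.33, ECSS 0.63, EOFS 0.70,
  ECFS 1.94 in/s by default).
* Each body-site accelerometer sees the second finite difference of the COP
  trace scaled by a site-specific coupling gain plus white sensor noise — a
  minimal lever-arm abstraction. Trunk-proximal sites (lumbar, ankle) couple
  strongly; distal sites (wrist, arm) weakly, so the sensor-placement
  ranking of the analysis is recoverable. The vertical axis carries noise
  only.
* Each subject carries one log-normal ability multiplier (mean 1, CV
  ``condition_av_cv``) shared across all four conditions, which induces the
  observed within-subject correlation of AV across conditions.

Sessions are produced as full sensor streams — lead-in padding, the four
condition blocks in test order with jittered durations, inter-condition
gaps, lead-out — together with cue timestamps, so cue segmentation and edge
trimming are exercised exactly as on real recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from . import posturography
from .errors import CalibrationError, InvalidParameterError
from .types import (
    CONDITIONS,
    PLACEMENTS,
    SENSOR_SLOTS,
    COPTrace,
    CueInterval,
    SensorRecording,
    SubjectRecord,
)

__all__ = [
    "SimConfig",
    "simulate_cop",
    "simulate_av_batch",
    "calibrate_scales",
    "cop_to_imu",
    "simulate_cohort",
]

#: study-condition mean AV targets, inches/second
DEFAULT_AV_TARGETS: dict[str, float] = {
    "EOSS": 0.33,
    "ECSS": 0.63,
    "EOFS": 0.70,
    "ECFS": 1.94,
}

#: coupling gains, ranked lumbar ≈ ankle > sternum > wrist > arm
DEFAULT_SITE_GAINS: dict[str, float] = {
    "lumbar": 1.0,
    "ankle": 0.95,
    "sternum": 0.6,
    "wrist": 0.25,
    "arm": 0.12,
}

#: additive white acceleration noise SD per site (arbitrary g-scaled units)
DEFAULT_SITE_NOISE_SD: dict[str, float] = {
    "lumbar": 3.0,
    "ankle": 3.0,
    "sternum": 3.0,
    "wrist": 10.0,
    "arm": 10.0,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``condition_av_cv`` is the coefficient of variation of the latent
    subject ability multiplier; the default 0.5 matches the roughly
    half-the-mean dispersion of the study conditions' AV scores.
    """

    n_subjects: int = 34
    duration_s: float = 11.0
    fs: float = 128.0
    condition_av_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AV_TARGETS)
    )
    condition_av_cv: float = 0.5
    mean_reversion_theta: float = 1.0  # 1/s
    site_gains: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_GAINS)
    )
    site_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_NOISE_SD)
    )
    left_handed_fraction: float = 3.0 / 34.0
    duration_jitter_s: float = 1.5  # uniform half-width on block duration
    lead_in_s: float = 2.0  # session padding before the first cue
    gap_s: float = 1.0  # padding between condition blocks
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise InvalidParameterError("n_subjects must be >= 2")
        if self.duration_s <= 0 or self.fs <= 0:
            raise InvalidParameterError("duration_s and fs must be positive")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                "fs * duration_s must be an integer sample count"
            )
        if set(self.condition_av_targets) != set(CONDITIONS):
            raise InvalidParameterError(
                f"condition_av_targets keys must be exactly {set(CONDITIONS)}"
            )
        if any(v <= 0 for v in self.condition_av_targets.values()):
            raise InvalidParameterError("AV targets must be strictly positive")
        for name, table in (
            ("site_gains", self.site_gains),
            ("site_noise_sd", self.site_noise_sd),
        ):
            if set(table) != set(PLACEMENTS):
                raise InvalidParameterError(
                    f"{name} must have one entry per placement"
                )
            if any(v <= 0 for v in table.values()):
                raise InvalidParameterError(f"{name} must be strictly positive")
        if not 0.0 <= self.left_handed_fraction <= 1.0:
            raise InvalidParameterError("left_handed_fraction must be in [0, 1]")
        if self.condition_av_cv < 0:
            raise InvalidParameterError("condition_av_cv must be >= 0")
        if self.mean_reversion_theta < 0:
            raise InvalidParameterError("mean_reversion_theta must be >= 0")
        if self.duration_jitter_s < 0 or self.duration_jitter_s >= self.duration_s:
            raise InvalidParameterError(
                "duration_jitter_s must be in [0, duration_s)"
            )


def _ou_paths(
    n_traces: int,
    n_samples: int,
    sway_scale: float,
    theta: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean-reverting random-walk paths, shape (n_traces, n_samples), x[0]=0.

    x[i+1] = x[i] * (1 - theta * dt) + sway_scale * sqrt(dt) * eta, an AR(1)
    recursion evaluated with a linear filter.
    """
    dt = 1.0 / fs
    a = 1.0 - theta * dt
    eta = rng.standard_normal((n_traces, n_samples - 1))
    steps = sway_scale * math.sqrt(dt) * eta
    tail = lfilter([1.0], [1.0, -a], steps, axis=1)
    return np.concatenate([np.zeros((n_traces, 1)), tail], axis=1)


def simulate_cop(
    sway_scale: float,
    duration_s: float,
    fs: float,
    theta: float = 1.0,
    rng: np.random.Generator | None = None,
) -> COPTrace:
    """Simulate one COP trace as independent ML/AP mean-reverting walks.

    Starts at (0, 0); the expected AV increases strictly with ``sway_scale``
    at fixed ``theta``, ``fs`` and duration (the recursion is linear in the
    scale).
    """
    if sway_scale <= 0:
        raise InvalidParameterError("sway_scale must be strictly positive")
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be strictly positive")
    n = int(round(fs * duration_s))
    if n < 2:
        raise InvalidParameterError("fs * duration_s must give >= 2 samples")
    rng = np.random.default_rng() if rng is None else rng
    xy = _ou_paths(2, n, sway_scale, theta, fs, rng)
    t = np.arange(n) / fs
    return COPTrace(t=t, x=xy[0], y=xy[1], fs=fs)


def simulate_av_batch(
    sway_scale: float,
    n_traces: int,
    duration_s: float,
    fs: float,
    theta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Average velocities of ``n_traces`` independent simulated traces."""
    if sway_scale <= 0 or n_traces < 1:
        raise InvalidParameterError("need sway_scale > 0 and n_traces >= 1")
    n = int(round(fs * duration_s))
    x = _ou_paths(n_traces, n, sway_scale, theta, fs, rng)
    y = _ou_paths(n_traces, n, sway_scale, theta, fs, rng)
    pl = np.hypot(np.diff(x, axis=1), np.diff(y, axis=1)).sum(axis=1)
    return pl / ((n - 1) / fs)


def calibrate_scales(
    config: SimConfig, n_traces: int = 500
) -> dict[str, float]:
    """Per-condition sway scales matching the configured mean-AV targets.

    AV is exactly proportional to ``sway_scale`` (the path recursion is
    linear in the scale and starts at zero), so the scale→AV map is a line
    through the origin: one seeded batch at unit scale fixes its slope, and
    each condition's scale is target / slope. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    av_unit = simulate_av_batch(
        1.0, n_traces, config.duration_s, config.fs,
        config.mean_reversion_theta, rng,
    )
    slope = float(av_unit.mean())
    if not math.isfinite(slope) or slope <= 0:
        raise CalibrationError("scale→AV map has no usable positive slope")
    return {
        cond: config.condition_av_targets[cond] / slope for cond in CONDITIONS
    }


def _block_second_difference(x: np.ndarray) -> np.ndarray:
    """Centred second difference with zeroed endpoints, same length as x."""
    d2 = np.zeros_like(x)
    if x.size >= 3:
        d2[1:-1] = x[2:] - 2.0 * x[1:-1] + x[:-2]
    return d2


def _device_axes(
    placement: str, ml: np.ndarray, ap: np.ndarray, vt: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map body-axis signals onto device axes X/Y/Z.

    All placements record X=ML, Y=AP, Z=VT except the upper arm, whose
    mounting swaps the horizontal axes: X=AP, Y=ML.
    """
    if placement == "arm":
        return ap, ml, vt
    return ml, ap, vt


def cop_to_imu(
    cop: COPTrace,
    placement: str,
    side: str,
    config: SimConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
    condition: str | None = None,
) -> SensorRecording:
    """Synthesise one sensor's acceleration from a COP trace.

    Per horizontal axis: acceleration = site gain × second finite difference
    of the COP coordinate × fs², plus white noise; the vertical axis is
    noise only. Output axes follow the device convention of the placement
    (see :func:`_device_axes`).
    """
    if placement not in PLACEMENTS:
        raise InvalidParameterError(f"unknown placement {placement!r}")
    gain = config.site_gains[placement]
    noise_sd = config.site_noise_sd[placement]
    fs2 = cop.fs**2
    ml = gain * _block_second_difference(cop.x) * fs2
    ap = gain * _block_second_difference(cop.y) * fs2
    vt = np.zeros_like(ml)
    noise = rng.normal(0.0, noise_sd, (3, cop.n_samples))
    x, y, z = _device_axes(placement, ml + noise[0], ap + noise[1], vt + noise[2])
    return SensorRecording(
        subject_id=subject_id,
        placement=placement,
        side=side,
        fs=cop.fs,
        t=cop.t.copy(),
        x=x,
        y=y,
        z=z,
        condition=condition,
    )


def _ability_multipliers(
    n: int, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal subject ability multipliers with mean 1 and CV ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv**2)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def _handedness_labels(config: SimConfig, rng: np.random.Generator) -> list[str]:
    """Exactly round(fraction × n) left-handers, positions shuffled."""
    n_left = int(round(config.left_handed_fraction * config.n_subjects))
    labels = ["left"] * n_left + ["right"] * (config.n_subjects - n_left)
    order = rng.permutation(config.n_subjects)
    return [labels[i] for i in order]


def simulate_cohort(
    config: SimConfig | None = None,
    scales: dict[str, float] | None = None,
) -> list[SubjectRecord]:
    """Simulate a full cohort of subjects with sessions, cues and scores.

    Each subject gets a latent ability multiplier applied to all four
    calibrated condition scales, a jittered block duration per condition,
    one COP trace per condition (ground-truth scores via the posturography
    module) and one full-session stream per sensor slot. Bit-reproducible
    for a fixed config.
    """
    config = SimConfig() if config is None else config
    config.validate()
    if scales is None:
        scales = calibrate_scales(config)

    root = np.random.SeedSequence([config.seed, 202])
    head_rng = np.random.default_rng(root.spawn(1)[0])
    handedness = _handedness_labels(config, head_rng)
    abilities = _ability_multipliers(
        config.n_subjects, config.condition_av_cv, head_rng
    )
    subject_seeds = root.spawn(config.n_subjects)

    fs = config.fs
    lead = int(round(config.lead_in_s * fs))
    gap = int(round(config.gap_s * fs))

    records: list[SubjectRecord] = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        subject_id = f"S{i + 1:03d}"
        record = SubjectRecord(
            subject_id=subject_id,
            handedness=handedness[i],
            ability=float(abilities[i]),
        )

        # jittered per-condition block lengths, in samples
        n_block: dict[str, int] = {}
        for cond in CONDITIONS:
            jitter = rng.uniform(-config.duration_jitter_s, config.duration_jitter_s)
            n_block[cond] = max(2, int(round(fs * (config.duration_s + jitter))))

        # session layout: lead-in, blocks with gaps, lead-out
        start = lead
        for cond in CONDITIONS:
            stop = start + n_block[cond]
            record.sample_ranges[cond] = (start, stop)
            record.cues.append(
                CueInterval(condition=cond, start_s=start / fs, stop_s=stop / fs)
            )
            start = stop + gap
        n_session = start - gap + lead  # reuse lead-in length as lead-out

        # per-condition COP traces and ground-truth scores
        for cond in CONDITIONS:
            scale = scales[cond] * abilities[i]
            cop = simulate_cop(
                scale,
                n_block[cond] / fs,
                fs,
                theta=config.mean_reversion_theta,
                rng=rng,
            )
            record.cop[cond] = cop
            record.scores[cond] = posturography.score_trace(cop, cond)

        # per-sensor full-session streams
        t_session = np.arange(n_session) / fs
        for placement, side in SENSOR_SLOTS:
            gain = config.site_gains[placement]
            noise_sd = config.site_noise_sd[placement]
            ml = np.zeros(n_session)
            ap = np.zeros(n_session)
            vt = np.zeros(n_session)
            fs2 = fs**2
            for cond in CONDITIONS:
                lo, hi = record.sample_ranges[cond]
                cop = record.cop[cond]
                ml[lo:hi] = gain * _block_second_difference(cop.x) * fs2
                ap[lo:hi] = gain * _block_second_difference(cop.y) * fs2
            noise = rng.normal(0.0, noise_sd, (3, n_session))
            x, y, z = _device_axes(
                placement, ml + noise[0], ap + noise[1], vt + noise[2]
            )
            record.sessions[(placement, side)] = SensorRecording(
                subject_id=subject_id,
                placement=placement,
                side=side,
                fs=fs,
                t=t_session,
                x=x,
                y=y,
                z=z,
            )
        records.append(record)
    return records
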