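"""Seeded synthetic generator for multimodal gait recordings.

The generator emulates the *structure* of the study data — 500 subjects x 5
activities x 3 trials, two time-aligned modalities per trial (8-channel EMG
at 2000 Hz, 7-channel wearable-robot stream at 71.42857 Hz), per-activity
trial durations and gait-cycle periods — with a controllable degree of
between-activity separability.  Waveform realism is explicitly not a goal;
the signal model is the simplest one that carries activity information the
way the real sensors do:

* hip angles: sinusoids at the gait-cycle period, left/right in anti-phase
  (alternating gait), with activity-specific amplitude and offset;
* angular velocities: the analytic time-derivative of the angles, in rpm;
* roll/yaw: small zero-mean oscillations; pitch: an activity-specific offset
  (positive for ascents, negative for descents; stairs additionally get a
  step-like ripple that distinguishes them from ramps);
* EMG: zero-mean noise amplitude-modulated by periodic per-muscle burst
  envelopes (VL/TA/BF/GAL x left/right) at activity-specific gains.

``class_separation`` linearly interpolates every activity-specific parameter
(including the per-activity duration and cycle-period distributions) between
the across-activity pooled value (separation 0: activities statistically
indistinguishable) and the configured per-activity value (separation 1, the
default).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .signals import (
    ACTIVITIES,
    EMG_CHANNELS,
    EMG_RATE_HZ,
    ROBOT_CHANNELS,
    ROBOT_RATE_HZ,
    DatasetManifest,
    ManifestEntry,
    Recording,
    write_recording,
)
from .windowing import WINDOW_SECONDS

# Per-activity trial duration mean/SD in seconds (EMG measurement-time rows).
DURATION_PARAMS_S: dict[str, tuple[float, float]] = {
    "LW": (4.81, 1.52), "SA": (4.65, 1.12), "SD": (4.6, 1.1),
    "RA": (4.9, 1.36), "RD": (4.34, 1.3),
}

# Per-activity gait-cycle period mean/SD in seconds (left-heel-strike rows).
CYCLE_PARAMS_S: dict[str, tuple[float, float]] = {
    "LW": (1.40, 0.33), "SA": (1.57, 0.40), "SD": (1.51, 0.32),
    "RA": (1.93, 0.47), "RD": (1.62, 0.48),
}

_MUSCLES = ("vl", "ta", "bf", "gal")


@dataclass(frozen=True)
class ActivityTemplate:
    """Deterministic shape parameters of one activity's signals."""

    hip_amplitude_deg: float
    hip_offset_deg: float
    pitch_offset_deg: float           # positive for ascents, negative for descents
    stair_ripple_deg: float           # step-like pitch ripple; non-zero for stairs
    burst_phases: dict[str, float]    # per muscle, fraction of the gait cycle
    burst_widths: dict[str, float]
    burst_gains: dict[str, float]


_BASE_PHASES = {"vl": 0.05, "ta": 0.70, "bf": 0.85, "gal": 0.45}
_BASE_WIDTHS = {"vl": 0.08, "ta": 0.10, "bf": 0.10, "gal": 0.12}

ACTIVITY_TEMPLATES: dict[str, ActivityTemplate] = {
    "LW": ActivityTemplate(20.0, 10.0, 0.0, 0.0, _BASE_PHASES, _BASE_WIDTHS,
                           {"vl": 1.2, "ta": 1.0, "bf": 0.8, "gal": 1.5}),
    "SA": ActivityTemplate(25.0, 15.0, 8.0, 2.0, _BASE_PHASES, _BASE_WIDTHS,
                           {"vl": 2.0, "ta": 0.9, "bf": 1.0, "gal": 2.2}),
    "SD": ActivityTemplate(17.0, 8.0, -8.0, 2.0, _BASE_PHASES, _BASE_WIDTHS,
                           {"vl": 1.5, "ta": 1.6, "bf": 1.1, "gal": 1.1}),
    "RA": ActivityTemplate(22.0, 13.0, 4.3, 0.0, _BASE_PHASES, _BASE_WIDTHS,
                           {"vl": 1.6, "ta": 1.0, "bf": 1.2, "gal": 1.9}),
    "RD": ActivityTemplate(18.0, 8.5, -4.3, 0.0, _BASE_PHASES, _BASE_WIDTHS,
                           {"vl": 1.1, "ta": 1.5, "bf": 0.7, "gal": 1.2}),
}


@dataclass
class GaitSimConfig:
    """Study-scale defaults: 500 subjects, 3 trials per activity, full separation."""

    n_subjects: int = 500
    trials_per_activity: int = 3
    duration_params_s: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DURATION_PARAMS_S))
    cycle_params_s: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CYCLE_PARAMS_S))
    class_separation: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for params in (self.duration_params_s, self.cycle_params_s):
            if any(sd < 0 for _, sd in params.values()):
                raise ValueError("standard deviations must be >= 0")

    def subject_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(1, self.n_subjects + 1)]


def _pooled(params: dict[str, tuple[float, float]]) -> tuple[float, float]:
    means = [m for m, _ in params.values()]
    sds = [s for _, s in params.values()]
    return float(np.mean(means)), float(np.mean(sds))


def _interp_params(params: dict[str, tuple[float, float]], activity: str,
                   sep: float) -> tuple[float, float]:
    pm, ps = _pooled(params)
    m, s = params[activity]
    return pm + sep * (m - pm), ps + sep * (s - ps)


def effective_template(activity: str, sep: float) -> ActivityTemplate:
    """Interpolate the activity template toward the across-activity mean."""
    base = ACTIVITY_TEMPLATES[activity]
    pooled_amp = float(np.mean([t.hip_amplitude_deg for t in ACTIVITY_TEMPLATES.values()]))
    pooled_off = float(np.mean([t.hip_offset_deg for t in ACTIVITY_TEMPLATES.values()]))
    pooled_pitch = float(np.mean([t.pitch_offset_deg for t in ACTIVITY_TEMPLATES.values()]))
    pooled_rip = float(np.mean([t.stair_ripple_deg for t in ACTIVITY_TEMPLATES.values()]))
    pooled_gain = {m: float(np.mean([t.burst_gains[m] for t in ACTIVITY_TEMPLATES.values()]))
                   for m in _MUSCLES}
    mix = lambda pooled, val: pooled + sep * (val - pooled)  # noqa: E731
    return replace(
        base,
        hip_amplitude_deg=mix(pooled_amp, base.hip_amplitude_deg),
        hip_offset_deg=mix(pooled_off, base.hip_offset_deg),
        pitch_offset_deg=mix(pooled_pitch, base.pitch_offset_deg),
        stair_ripple_deg=mix(pooled_rip, base.stair_ripple_deg),
        burst_gains={m: mix(pooled_gain[m], base.burst_gains[m]) for m in _MUSCLES},
    )


def _trial_rng(cfg: GaitSimConfig, subject_id: str, activity: str,
               trial_index: int) -> np.random.Generator:
    key = (cfg.seed, zlib.crc32(subject_id.encode()),
           ACTIVITIES.index(activity), trial_index)
    return np.random.default_rng(np.random.SeedSequence(key))


def _subject_rng(cfg: GaitSimConfig, subject_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((cfg.seed, zlib.crc32(subject_id.encode()), 77)))


def sample_duration(activity: str, cfg: GaitSimConfig,
                    rng: np.random.Generator) -> float:
    """Trial duration in seconds: Normal(mean_a, sd_a) clamped below at one
    window length, so segmentation always yields at least one window."""
    mean, sd = _interp_params(cfg.duration_params_s, activity, cfg.class_separation)
    return max(WINDOW_SECONDS, float(rng.normal(mean, sd)))


def sample_cycle_period(activity: str, cfg: GaitSimConfig,
                        rng: np.random.Generator) -> float:
    mean, sd = _interp_params(cfg.cycle_params_s, activity, cfg.class_separation)
    return max(0.4, float(rng.normal(mean, sd)))


def _burst_envelope(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic Gaussian bump on the unit circle of gait phase."""
    env = np.zeros_like(phase)
    for k in (-1.0, 0.0, 1.0):
        env += np.exp(-0.5 * ((phase - center + k) / width) ** 2)
    return env


def simulate_trial(subject_id: str, activity: str, trial_index: int,
                   cfg: GaitSimConfig, rng: np.random.Generator | None = None,
                   ) -> tuple[Recording, Recording]:
    """One trial in both modalities, time-aligned and deterministic per
    (subject, activity, trial, seed)."""
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}")
    rng = rng or _trial_rng(cfg, subject_id, activity, trial_index)
    srng = _subject_rng(cfg, subject_id)
    phi = srng.uniform(0.0, 2.0 * np.pi)          # subject-specific gait phase
    amp_factor = srng.normal(1.0, 0.05)           # subject-specific gain

    tpl = effective_template(activity, cfg.class_separation)
    duration = sample_duration(activity, cfg, rng)
    period = sample_cycle_period(activity, cfg, rng)

    n_robot = int(np.floor(duration * ROBOT_RATE_HZ))
    n_emg = int(np.floor(duration * EMG_RATE_HZ))
    t_robot = np.arange(n_robot) / ROBOT_RATE_HZ
    t_emg = np.arange(n_emg) / EMG_RATE_HZ

    def robot_noise(n: int) -> np.ndarray:
        # clipped so angle channels stay within offset +- amplitude +- 3*noise_sd
        return np.clip(rng.normal(0.0, cfg.noise_sd, n), -3 * cfg.noise_sd, 3 * cfg.noise_sd)

    omega = 2.0 * np.pi / period
    amp = tpl.hip_amplitude_deg * amp_factor
    angle_l = tpl.hip_offset_deg + amp * np.sin(omega * t_robot + phi)
    angle_r = tpl.hip_offset_deg + amp * np.sin(omega * t_robot + phi + np.pi)
    # rpm = (deg/s) / 360 * 60
    vel_l = amp * omega * np.cos(omega * t_robot + phi) / 6.0
    vel_r = amp * omega * np.cos(omega * t_robot + phi + np.pi) / 6.0
    roll = 1.5 * np.sin(2.0 * omega * t_robot + phi * 0.5)
    yaw = 1.2 * np.sin(omega * t_robot + phi * 0.25)
    pitch = tpl.pitch_offset_deg + 1.0 * np.sin(omega * t_robot + phi)
    if tpl.stair_ripple_deg:
        pitch = pitch + tpl.stair_ripple_deg * np.sign(np.sin(omega * t_robot + phi))
    robot_samples = np.column_stack([
        angle_l + robot_noise(n_robot), angle_r + robot_noise(n_robot),
        vel_l + robot_noise(n_robot), vel_r + robot_noise(n_robot),
        roll + robot_noise(n_robot), pitch + robot_noise(n_robot),
        yaw + robot_noise(n_robot)])

    phase_l = np.mod(t_emg / period + phi / (2.0 * np.pi), 1.0)
    phase_r = np.mod(phase_l + 0.5, 1.0)
    emg_cols = []
    for muscle in _MUSCLES:
        c, w, g = tpl.burst_phases[muscle], tpl.burst_widths[muscle], tpl.burst_gains[muscle]
        for phase in (phase_l, phase_r):
            env = 0.2 + g * _burst_envelope(phase, c, w)
            emg_cols.append(cfg.noise_sd * env * rng.normal(0.0, 1.0, n_emg))
    emg_samples = np.column_stack(emg_cols)

    common = dict(subject_id=subject_id, activity=activity, trial_index=trial_index)
    emg = Recording(modality="emg", sampling_rate_hz=EMG_RATE_HZ,
                    channel_names=EMG_CHANNELS, samples=emg_samples, **common)
    robot = Recording(modality="robot", sampling_rate_hz=ROBOT_RATE_HZ,
                      channel_names=ROBOT_CHANNELS, samples=robot_samples, **common)
    return emg, robot


def iter_trials(cfg: GaitSimConfig):
    """Yield (subject_id, activity, trial_index) in canonical order."""
    for subject_id in cfg.subject_ids():
        for activity in ACTIVITIES:
            for trial_index in range(1, cfg.trials_per_activity + 1):
                yield subject_id, activity, trial_index


def simulate_recordings(cfg: GaitSimConfig):
    """In-memory generator of (emg, robot) recording pairs."""
    for subject_id, activity, trial_index in iter_trials(cfg):
        yield simulate_trial(subject_id, activity, trial_index, cfg)


def simulate_dataset(cfg: GaitSimConfig, out_dir: str | Path,
                     modalities: tuple[str, ...] = ("emg", "robot"),
                     ) -> tuple[DatasetManifest, dict]:
    """Write the dataset (CSV per trial and modality + JSON manifest).

    Returns the manifest and per-activity duration summary statistics.
    """
    if cfg.n_subjects < 10:
        raise ValueError("need n_subjects >= 10 for meaningful subject splits")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    durations: dict[str, list[float]] = {a: [] for a in ACTIVITIES}
    for emg, robot in simulate_recordings(cfg):
        for rec in (emg, robot):
            if rec.modality not in modalities:
                continue
            fname = (f"{rec.subject_id}_{rec.activity}_t{rec.trial_index}"
                     f"_{rec.modality}.csv")
            write_recording(rec, out_dir / fname)
            entries.append(ManifestEntry(
                path=fname, subject_id=rec.subject_id, activity=rec.activity,
                trial_index=rec.trial_index, modality=rec.modality,
                sampling_rate_hz=rec.sampling_rate_hz,
                channel_names=tuple(rec.channel_names)))
        durations[robot.activity].append(robot.duration_s)
    manifest = DatasetManifest(entries)
    manifest.to_json(out_dir / "manifest.json")
    summary = {
        "per_activity_duration_s": {
            a: {"mean": float(np.mean(v)), "sd": float(np.std(v)), "n": len(v)}
            for a, v in durations.items()},
        "pooled_duration_mean_s": float(np.mean(np.concatenate(
            [np.asarray(v) for v in durations.values()]))),
        "n_trials": sum(len(v) for v in durations.values()),
    }
    return manifest, summary
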