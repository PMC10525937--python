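"""Recordings, dataset manifests, and min-max normalization.

A *recording* is one trial of one modality: either the 8-channel surface-EMG
stream at 2000 Hz (vastus lateralis, tibialis anterior, biceps femoris and
gastrocnemius lateralis of both legs) or the 7-channel wearable-robot stream
at 71.42857 Hz (left/right hip angle in degrees, left/right angular velocity
in rpm, and roll/pitch/yaw posture in degrees).  Activities are the five
locomotion modes: level walking (LW), stair ascent/descent (SA/SD) and ramp
ascent/descent (RA/RD).

Signals are used raw — no filtering — and normalized per channel to
[-1, 1] with min/max statistics computed on the *training* recordings only;
values outside the training range at apply time are clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ACTIVITIES: tuple[str, ...] = ("LW", "SA", "SD", "RA", "RD")

EMG_RATE_HZ = 2000.0
ROBOT_RATE_HZ = 71.42857

EMG_CHANNELS: tuple[str, ...] = (
    "emg_vl_l", "emg_vl_r", "emg_ta_l", "emg_ta_r",
    "emg_bf_l", "emg_bf_r", "emg_gal_l", "emg_gal_r",
)
ROBOT_CHANNELS: tuple[str, ...] = (
    "hip_angle_l_deg", "hip_angle_r_deg",
    "velocity_l_rpm", "velocity_r_rpm",
    "roll_deg", "pitch_deg", "yaw_deg",
)

MODALITY_RATES = {"emg": EMG_RATE_HZ, "robot": ROBOT_RATE_HZ}
MODALITY_CHANNELS = {"emg": EMG_CHANNELS, "robot": ROBOT_CHANNELS}


class RecordingError(ValueError):
    """Base class for recording contract violations."""


class MissingFileError(RecordingError):
    pass


class ChannelCountError(RecordingError):
    pass


class NonNumericValueError(RecordingError):
    pass


class MissingValueError(RecordingError):
    pass


@dataclass
class Recording:
    """One trial's multichannel signal with its metadata.

    ``samples`` is a (time, channels) float array; row count divided by the
    sampling rate is the trial duration in seconds.
    """

    subject_id: str
    activity: str
    trial_index: int
    modality: str
    sampling_rate_hz: float
    channel_names: tuple[str, ...]
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise RecordingError(f"unknown activity {self.activity!r}")
        if self.modality not in MODALITY_RATES:
            raise RecordingError(f"unknown modality {self.modality!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise RecordingError("samples must be a non-empty (time, channels) matrix")
        expected_c = len(MODALITY_CHANNELS[self.modality])
        if self.samples.shape[1] != expected_c or len(self.channel_names) != expected_c:
            raise ChannelCountError(
                f"{self.modality} recording must have {expected_c} channels, "
                f"got {self.samples.shape[1]}")
        expected_rate = MODALITY_RATES[self.modality]
        if abs(self.sampling_rate_hz - expected_rate) > 1e-6:
            raise RecordingError(
                f"{self.modality} recordings are sampled at {expected_rate} Hz")
        if np.isnan(self.samples).any():
            raise MissingValueError("recording contains missing values")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.sampling_rate_hz

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.subject_id, self.activity, self.trial_index, self.modality)


@dataclass
class ManifestEntry:
    path: str
    subject_id: str
    activity: str
    trial_index: int
    modality: str
    sampling_rate_hz: float
    channel_names: tuple[str, ...]

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.subject_id, self.activity, self.trial_index, self.modality)


@dataclass
class DatasetManifest:
    """Index of a dataset directory: one entry per (trial, modality) file."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise RecordingError("duplicate (subject, activity, trial, modality) in manifest")

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.subject_id, None)
        return list(seen)

    def select(self, modality: str | None = None, subjects=None) -> list[ManifestEntry]:
        subjects = set(subjects) if subjects is not None else None
        return [e for e in self.entries
                if (modality is None or e.modality == modality)
                and (subjects is None or e.subject_id in subjects)]

    def to_json(self, path: str | Path) -> None:
        payload = [{**e.__dict__, "channel_names": list(e.channel_names)}
                   for e in self.entries]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        entries = [ManifestEntry(**{**d, "channel_names": tuple(d["channel_names"])})
                   for d in payload]
        return cls(entries)


def write_recording(rec: Recording, path: str | Path) -> None:
    """CSV with a header row of channel names, one sample per row.

    Values are written with 17 significant digits, so a write/read cycle
    reproduces float64 samples bit-identically.
    """
    df = pd.DataFrame(rec.samples, columns=list(rec.channel_names))
    df.to_csv(path, index=False, float_format="%.17g")


def read_recording(path: str | Path, entry: ManifestEntry) -> Recording:
    """Read one trial CSV using the manifest entry's metadata.

    Raises :class:`MissingFileError`, :class:`ChannelCountError`,
    :class:`NonNumericValueError` or :class:`MissingValueError` on the
    corresponding contract violation.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"recording file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    expected_c = len(MODALITY_CHANNELS[entry.modality])
    if df.shape[1] != expected_c:
        raise ChannelCountError(
            f"{path}: expected {expected_c} channels for modality "
            f"{entry.modality!r}, found {df.shape[1]}")
    try:
        samples = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise NonNumericValueError(f"{path}: non-numeric cell ({exc})") from None
    if np.isnan(samples).any():
        raise MissingValueError(f"{path}: missing value")
    return Recording(
        subject_id=entry.subject_id,
        activity=entry.activity,
        trial_index=entry.trial_index,
        modality=entry.modality,
        sampling_rate_hz=entry.sampling_rate_hz,
        channel_names=tuple(entry.channel_names),
        samples=samples,
    )


@dataclass
class NormalizationStats:
    """Per-modality, per-channel min/max plus the split they came from.

    The leakage contract: statistics are computed only from training-split
    recordings and then applied unchanged to validation/test data.
    """

    minima: dict[str, np.ndarray]
    maxima: dict[str, np.ndarray]
    provenance: str = "train"

    def __post_init__(self) -> None:
        for mod in self.minima:
            if np.any(self.minima[mod] > self.maxima[mod]):
                raise ValueError(f"min > max in normalization stats for {mod!r}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "provenance": self.provenance,
            "minima": {m: v.tolist() for m, v in self.minima.items()},
            "maxima": {m: v.tolist() for m, v in self.maxima.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        d = json.loads(Path(path).read_text())
        return cls(minima={m: np.asarray(v) for m, v in d["minima"].items()},
                   maxima={m: np.asarray(v) for m, v in d["maxima"].items()},
                   provenance=d["provenance"])


def compute_normalization_stats(train_recordings: list[Recording],
                                provenance: str = "train") -> NormalizationStats:
    """Global per-channel extrema across all training recordings per modality."""
    if not train_recordings:
        raise ValueError("cannot compute normalization stats from an empty list")
    minima: dict[str, np.ndarray] = {}
    maxima: dict[str, np.ndarray] = {}
    layouts: dict[str, tuple[str, ...]] = {}
    for rec in train_recordings:
        layout = tuple(rec.channel_names)
        if rec.modality in layouts and layouts[rec.modality] != layout:
            raise ValueError(f"mixed channel layouts for modality {rec.modality!r}")
        layouts[rec.modality] = layout
        lo = rec.samples.min(axis=0)
        hi = rec.samples.max(axis=0)
        if rec.modality in minima:
            minima[rec.modality] = np.minimum(minima[rec.modality], lo)
            maxima[rec.modality] = np.maximum(maxima[rec.modality], hi)
        else:
            minima[rec.modality] = lo
            maxima[rec.modality] = hi
    return NormalizationStats(minima=minima, maxima=maxima, provenance=provenance)


def apply_normalization(rec: Recording, stats: NormalizationStats) -> Recording:
    """Map each value to 2*(x - min)/(max - min) - 1, clipped to [-1, 1].

    Channels whose training min equals their max carry no information and map
    to 0, the center of the target range.
    """
    if rec.modality not in stats.minima:
        raise KeyError(f"no normalization stats for modality {rec.modality!r}")
    lo = stats.minima[rec.modality]
    hi = stats.maxima[rec.modality]
    span = hi - lo
    degenerate = span == 0
    safe_span = np.where(degenerate, 1.0, span)
    scaled = 2.0 * (rec.samples - lo) / safe_span - 1.0
    scaled = np.where(degenerate, 0.0, scaled)
    scaled = np.clip(scaled, -1.0, 1.0)
    return Recording(
        subject_id=rec.subject_id,
        activity=rec.activity,
        trial_index=rec.trial_index,
        modality=rec.modality,
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_names=rec.channel_names,
        samples=scaled,
    )
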