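"""Sliding-window segmentation and subject-grouped 8:1:1 partitioning.

Windows are 1.76 s long with an overlap ratio of 0.9 between consecutive
windows, giving 3520-sample EMG windows and 125-sample wearable-robot
windows at their respective rates.  Partitioning is by *subject* so that no
individual contributes windows to more than one of train/validation/test —
the leakage guard standard in activity recognition.

For multi-head training the EMG and robot streams of a trial are paired by
window ordinal with time-anchored start indices, so window *i* covers the
same 1.76 s interval in both modalities (starts agree within one robot
sample period).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signals import ACTIVITIES, Recording

logger = logging.getLogger(__name__)

WINDOW_SECONDS = 1.76
OVERLAP_RATIO = 0.9


def window_length(rate_hz: float, window_seconds: float = WINDOW_SECONDS) -> int:
    """Window length in samples: floor(rate * window_seconds).

    floor (not round) is what reproduces the published 125-sample robot
    window at 71.42857 Hz (125.71 -> 125).
    """
    if rate_hz <= 0 or window_seconds <= 0:
        raise ValueError("rate and window duration must be positive")
    return math.floor(rate_hz * window_seconds)


def window_step(rate_hz: float, window_seconds: float = WINDOW_SECONDS,
                overlap_ratio: float = OVERLAP_RATIO) -> int:
    """Stride in samples; overlap is the fraction shared with the successor."""
    if not 0.0 <= overlap_ratio < 1.0:
        raise ValueError("overlap ratio must lie in [0, 1)")
    w = window_length(rate_hz, window_seconds)
    # epsilon guard: 3520 * (1 - 0.9) is 351.999... in binary floating point
    return max(1, math.floor(w * (1.0 - overlap_ratio) + 1e-9))


@dataclass
class WindowSet:
    """Segmented, labeled, subject-tagged windows of one modality."""

    modality: str
    windows: np.ndarray            # (n, T, C) float32
    labels: np.ndarray             # (n,) activity strings
    subject_ids: np.ndarray        # (n,) strings
    start_indices: np.ndarray      # (n,) sample index of each window start
    trial_keys: np.ndarray         # (n,) "subject/activity/trial" strings
    window_seconds: float = WINDOW_SECONDS
    overlap_ratio: float = OVERLAP_RATIO

    def __post_init__(self) -> None:
        n = self.windows.shape[0]
        for name in ("labels", "subject_ids", "start_indices", "trial_keys"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal the number of windows")

    @property
    def n_windows(self) -> int:
        return int(self.windows.shape[0])

    def label_distribution(self) -> dict[str, int]:
        return {a: int((self.labels == a).sum()) for a in ACTIVITIES}

    @classmethod
    def concatenate(cls, parts: list["WindowSet"]) -> "WindowSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        return cls(
            modality=first.modality,
            windows=np.concatenate([p.windows for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            start_indices=np.concatenate([p.start_indices for p in parts]),
            trial_keys=np.concatenate([p.trial_keys for p in parts]),
            window_seconds=first.window_seconds,
            overlap_ratio=first.overlap_ratio,
        )

    def save(self, path: str | Path) -> None:
        """Binary container (npz) with a JSON sidecar header."""
        path = Path(path)
        np.savez_compressed(
            path, windows=self.windows.astype(np.float32), labels=self.labels,
            subject_ids=self.subject_ids, start_indices=self.start_indices,
            trial_keys=self.trial_keys)
        header = {
            "modality": self.modality, "shape": list(self.windows.shape),
            "dtype": "float32", "window_seconds": self.window_seconds,
            "overlap_ratio": self.overlap_ratio, "label_set": list(ACTIVITIES),
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            return cls(
                modality=header["modality"], windows=z["windows"],
                labels=z["labels"], subject_ids=z["subject_ids"],
                start_indices=z["start_indices"], trial_keys=z["trial_keys"],
                window_seconds=header["window_seconds"],
                overlap_ratio=header["overlap_ratio"])


def _empty_windowset(rec: Recording, w: int, window_seconds: float,
                     overlap_ratio: float) -> WindowSet:
    c = rec.samples.shape[1]
    return WindowSet(
        modality=rec.modality,
        windows=np.empty((0, w, c), dtype=np.float32),
        labels=np.empty(0, dtype="<U2"),
        subject_ids=np.empty(0, dtype=str),
        start_indices=np.empty(0, dtype=int),
        trial_keys=np.empty(0, dtype=str),
        window_seconds=window_seconds,
        overlap_ratio=overlap_ratio,
    )


def _slice_windows(rec: Recording, starts: np.ndarray, w: int,
                   window_seconds: float, overlap_ratio: float) -> WindowSet:
    key = f"{rec.subject_id}/{rec.activity}/{rec.trial_index}"
    windows = np.stack([rec.samples[s:s + w] for s in starts]).astype(np.float32)
    n = len(starts)
    return WindowSet(
        modality=rec.modality,
        windows=windows,
        labels=np.full(n, rec.activity),
        subject_ids=np.full(n, rec.subject_id),
        start_indices=np.asarray(starts, dtype=int),
        trial_keys=np.full(n, key),
        window_seconds=window_seconds,
        overlap_ratio=overlap_ratio,
    )


def make_windows(rec: Recording, window_seconds: float = WINDOW_SECONDS,
                 overlap_ratio: float = OVERLAP_RATIO) -> WindowSet:
    """Uniform-stride segmentation of one (normalized) recording.

    Start indices are 0, s, 2s, ... with s = max(1, floor(W*(1-overlap))),
    every window fully inside the trial; a trial shorter than one window
    yields zero windows and a logged warning.
    """
    w = window_length(rec.sampling_rate_hz, window_seconds)
    s = window_step(rec.sampling_rate_hz, window_seconds, overlap_ratio)
    L = rec.samples.shape[0]
    if L < w:
        logger.warning("trial %s/%s/%d shorter than one window (%d < %d): 0 windows",
                       rec.subject_id, rec.activity, rec.trial_index, L, w)
        return _empty_windowset(rec, w, window_seconds, overlap_ratio)
    starts = np.arange(0, L - w + 1, s)
    return _slice_windows(rec, starts, w, window_seconds, overlap_ratio)


def make_aligned_windows(emg: Recording, robot: Recording,
                         window_seconds: float = WINDOW_SECONDS,
                         overlap_ratio: float = OVERLAP_RATIO,
                         ) -> tuple[WindowSet, WindowSet]:
    """Paired segmentation of a trial's two modalities.

    Window *i* starts at time i * window_seconds * (1 - overlap); each
    modality takes the window beginning at floor(start_time * rate), so the
    two start times agree within one robot sample period.  Trailing windows
    that fit only one modality are dropped from both.
    """
    if emg.key[:3] != robot.key[:3]:
        raise ValueError("aligned windowing needs the same trial in both modalities")
    w_e = window_length(emg.sampling_rate_hz, window_seconds)
    w_r = window_length(robot.sampling_rate_hz, window_seconds)
    if not 0.0 <= overlap_ratio < 1.0:
        raise ValueError("overlap ratio must lie in [0, 1)")
    step_sec = window_seconds * (1.0 - overlap_ratio)
    starts_e, starts_r = [], []
    i = 0
    while True:
        t0 = i * step_sec
        s_e = math.floor(t0 * emg.sampling_rate_hz + 1e-9)
        s_r = math.floor(t0 * robot.sampling_rate_hz + 1e-9)
        if s_e + w_e > emg.samples.shape[0] or s_r + w_r > robot.samples.shape[0]:
            break
        starts_e.append(s_e)
        starts_r.append(s_r)
        i += 1
    if not starts_e:
        logger.warning("trial %s/%s/%d shorter than one window in one modality",
                       emg.subject_id, emg.activity, emg.trial_index)
        return (_empty_windowset(emg, w_e, window_seconds, overlap_ratio),
                _empty_windowset(robot, w_r, window_seconds, overlap_ratio))
    return (_slice_windows(emg, np.asarray(starts_e), w_e, window_seconds, overlap_ratio),
            _slice_windows(robot, np.asarray(starts_r), w_r, window_seconds, overlap_ratio))


@dataclass
class SplitSpec:
    """Disjoint train/validation/test subject rosters."""

    train_subjects: tuple[str, ...]
    val_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train_subjects), set(self.val_subjects), set(self.test_subjects)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split subject sets must be pairwise disjoint")

    def split_of(self, subject_id: str) -> str | None:
        if subject_id in set(self.train_subjects):
            return "train"
        if subject_id in set(self.val_subjects):
            return "val"
        if subject_id in set(self.test_subjects):
            return "test"
        return None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train_subjects": list(self.train_subjects),
            "val_subjects": list(self.val_subjects),
            "test_subjects": list(self.test_subjects),
            "seed": self.seed}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["train_subjects"]), tuple(d["val_subjects"]),
                   tuple(d["test_subjects"]), d["seed"])


def group_split(roster: list[str], ratios: tuple[float, float, float] = (8, 1, 1),
                seed: int = 0) -> SplitSpec:
    """Deterministic subject-level split at the given ratios.

    Validation/test sizes are round(share * N); the remainder goes to train
    (the largest share), so 500 subjects split 400/50/50.
    """
    if len(set(roster)) != len(roster):
        raise ValueError("duplicate subject ids in roster")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    n = len(roster)
    if n < 3:
        raise ValueError("roster smaller than the number of splits")
    total = sum(ratios)
    n_val = round(ratios[1] / total * n)
    n_test = round(ratios[2] / total * n)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of {n} subjects leaves an empty partition")
    rng = np.random.default_rng(seed)
    order = list(np.array(sorted(roster))[rng.permutation(n)])
    return SplitSpec(
        train_subjects=tuple(order[:n_train]),
        val_subjects=tuple(order[n_train:n_train + n_val]),
        test_subjects=tuple(order[n_train + n_val:]),
        seed=seed,
    )


def assemble(split: SplitSpec, trial_windowsets: list[WindowSet],
             ) -> dict[str, dict[str, WindowSet]]:
    """Merge per-trial WindowSets into {train, val, test} per modality.

    Every window's subject must belong to exactly one split (an error names
    any subject in none).  When both modalities of a trial are present their
    window counts are trimmed to the shorter so multi-head inputs stay
    index-aligned.  Per-split label frequencies are logged.
    """
    by_trial: dict[str, dict[str, WindowSet]] = {}
    for ws in trial_windowsets:
        if ws.n_windows == 0:
            continue
        keys = set(ws.trial_keys.tolist())
        if len(keys) != 1:
            raise ValueError("assemble expects per-trial WindowSets")
        by_trial.setdefault(keys.pop(), {})[ws.modality] = ws

    out: dict[str, dict[str, list[WindowSet]]] = {
        s: {} for s in ("train", "val", "test")}
    for key in sorted(by_trial):
        mods = by_trial[key]
        subject = next(iter(mods.values())).subject_ids[0]
        part = split.split_of(subject)
        if part is None:
            raise ValueError(f"subject {subject!r} is present in no split")
        n_keep = min(ws.n_windows for ws in mods.values())
        for mod, ws in mods.items():
            trimmed = WindowSet(
                modality=ws.modality, windows=ws.windows[:n_keep],
                labels=ws.labels[:n_keep], subject_ids=ws.subject_ids[:n_keep],
                start_indices=ws.start_indices[:n_keep],
                trial_keys=ws.trial_keys[:n_keep],
                window_seconds=ws.window_seconds, overlap_ratio=ws.overlap_ratio)
            out[part].setdefault(mod, []).append(trimmed)

    result: dict[str, dict[str, WindowSet]] = {}
    for part, mods in out.items():
        result[part] = {mod: WindowSet.concatenate(parts) for mod, parts in mods.items()}
        for mod, ws in result[part].items():
            logger.info("%s/%s: %d windows %s", part, mod, ws.n_windows,
                        ws.label_distribution())
    # leakage guard: asserted on every assembled dataset
    subject_sets = [
        {s for mod_ws in result[p].values() for s in set(mod_ws.subject_ids.tolist())}
        for p in result]
    for a in range(len(subject_sets)):
        for b in range(a + 1, len(subject_sets)):
            if subject_sets[a] & subject_sets[b]:
                raise AssertionError("subject leakage across splits")
    return result
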