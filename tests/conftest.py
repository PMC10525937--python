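"""Shared fixtures: tiny synthetic datasets built in memory at test time."""

from __future__ import annotations

import numpy as np
import pytest

from gaitnet.gaitsim import GaitSimConfig, simulate_recordings
from gaitnet.signals import apply_normalization, compute_normalization_stats
from gaitnet.windowing import assemble, group_split, make_windows


def build_robot_splits(n_subjects: int, class_separation: float, sim_seed: int,
                       split_seed: int):
    """Simulate -> normalize (train stats) -> window -> subject-grouped splits,
    robot modality only."""
    cfg = GaitSimConfig(n_subjects=n_subjects, seed=sim_seed,
                        class_separation=class_separation)
    robots = [robot for _, robot in simulate_recordings(cfg)]
    split = group_split(cfg.subject_ids(), seed=split_seed)
    train_recs = [r for r in robots if r.subject_id in split.train_subjects]
    stats = compute_normalization_stats(train_recs)
    windows = [make_windows(apply_normalization(r, stats)) for r in robots]
    return assemble(split, windows)


@pytest.fixture(scope="session")
def tiny_robot_splits():
    """10 subjects at full class separation; ~2000 windows of (125, 7)."""
    return build_robot_splits(n_subjects=10, class_separation=1.0,
                              sim_seed=11, split_seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
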