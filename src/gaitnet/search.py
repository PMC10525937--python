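"""Structural hyperparameter search over the constrained architecture space.

The space is conditional: per-block and per-layer choices exist only for
instantiated blocks/layers.  Each configuration is encoded as a dictionary
of categorical choices — block/layer counts, a starting width plus a chain
of up/down twofold moves (reflected at the ends of the allowed sets, so
every sampled point is valid by construction), pooling types, learning rate
and batch size.

The optimizer is a tree-structured Parzen estimator for categorical
variables: past trials are split at the gamma-quantile of the score into
good and bad sets; each conditional dimension gets smoothed categorical
densities l(x) (good) and g(x) (bad); candidates are drawn from l and the
one maximizing sum log l/g is evaluated next.  Plain random search is
available as an alternative.  The objective is the validation macro
F-measure of a 20-epoch training run; failing trials (for example a spec
whose pooling collapses the short robot windows) score -inf and the search
continues.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .fit_eval import evaluate_model, to_arrays
from .nets import (
    ArchSpec, BATCH_SIZE_CHOICES, ConvBlockSpec, DENSE_CHOICES, FILTER_CHOICES,
    LEARNING_RATE_CHOICES, TemporalCollapseError, build_from_spec,
)
from .nn import fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchSpace:
    """The structural search space (counts, widths, pooling, training knobs)."""

    max_blocks: int = 3
    max_convs_per_block: int = 3
    filter_choices: tuple[int, ...] = FILTER_CHOICES
    pooling_choices: tuple[str, ...] = ("max", "average")
    max_dense_layers: int = 3
    dense_choices: tuple[int, ...] = DENSE_CHOICES
    learning_rates: tuple[float, ...] = LEARNING_RATE_CHOICES
    batch_sizes: tuple[int, ...] = BATCH_SIZE_CHOICES
    trial_epochs: int = 20


@dataclass
class TrialResult:
    """One search evaluation: the sampled point and its quality score."""

    config: dict
    spec: dict
    y: float                      # validation macro F-measure (or -inf on failure)
    val_loss: float
    trial_index: int
    seed: int
    status: str = "ok"
    error: str = ""

    def to_json_line(self) -> str:
        d = asdict(self)
        if not math.isfinite(d["y"]):
            d["y"] = None
        if not math.isfinite(d["val_loss"]):
            d["val_loss"] = None
        return json.dumps(d)


# ---------------------------------------------------------------------------
# Configuration encoding
# ---------------------------------------------------------------------------

def _walk_chain(start: int, moves: list[str], choices: tuple[int, ...]) -> list[int]:
    """Apply twofold up/down moves, reflecting at the ends of the set."""
    chain = [start]
    for mv in moves:
        nxt = chain[-1] * 2 if mv == "up" else chain[-1] // 2
        if nxt not in choices:
            nxt = chain[-1] // 2 if mv == "up" else chain[-1] * 2
        chain.append(nxt)
    return chain


def _dimension_domain(key: str, space: SearchSpace) -> tuple:
    if key.endswith(".n_blocks"):
        return tuple(range(1, space.max_blocks + 1))
    if ".n_convs" in key:
        return tuple(range(1, space.max_convs_per_block + 1))
    if ".pooling" in key:
        return space.pooling_choices
    if key.endswith("filters.start"):
        return space.filter_choices
    if key == "dense.start":
        return space.dense_choices
    if ".dir" in key:
        return ("up", "down")
    if key == "n_dense":
        return tuple(range(1, space.max_dense_layers + 1))
    if key == "learning_rate":
        return space.learning_rates
    if key == "batch_size":
        return space.batch_sizes
    raise KeyError(key)


def sample_config(space: SearchSpace, rng: np.random.Generator,
                  modalities: tuple[str, ...] = ("robot",)) -> dict:
    """Random point in the conditional space (always valid)."""
    def pick(key):
        domain = _dimension_domain(key, space)
        return domain[rng.integers(len(domain))]

    cfg: dict = {}
    for m in modalities:
        n_blocks = pick(f"{m}.n_blocks")
        cfg[f"{m}.n_blocks"] = n_blocks
        total_convs = 0
        for b in range(n_blocks):
            n_convs = pick(f"{m}.block{b}.n_convs")
            cfg[f"{m}.block{b}.n_convs"] = n_convs
            cfg[f"{m}.block{b}.pooling"] = pick(f"{m}.block{b}.pooling")
            total_convs += n_convs
        cfg[f"{m}.filters.start"] = pick(f"{m}.filters.start")
        for j in range(total_convs - 1):
            cfg[f"{m}.filters.dir{j}"] = pick(f"{m}.filters.dir{j}")
    n_dense = pick("n_dense")
    cfg["n_dense"] = n_dense
    cfg["dense.start"] = pick("dense.start")
    for j in range(n_dense - 1):
        cfg[f"dense.dir{j}"] = pick(f"dense.dir{j}")
    cfg["learning_rate"] = pick("learning_rate")
    cfg["batch_size"] = pick("batch_size")
    return cfg


def config_to_spec(cfg: dict, space: SearchSpace,
                   modalities: tuple[str, ...] = ("robot",)) -> ArchSpec:
    """Decode a configuration dict into a validated ArchSpec."""
    heads = {}
    for m in modalities:
        n_blocks = cfg[f"{m}.n_blocks"]
        convs = [cfg[f"{m}.block{b}.n_convs"] for b in range(n_blocks)]
        moves = [cfg[f"{m}.filters.dir{j}"] for j in range(sum(convs) - 1)]
        chain = _walk_chain(cfg[f"{m}.filters.start"], moves, space.filter_choices)
        blocks = []
        i = 0
        for b, n_convs in enumerate(convs):
            blocks.append(ConvBlockSpec(tuple(chain[i:i + n_convs]),
                                        pooling=cfg[f"{m}.block{b}.pooling"]))
            i += n_convs
        heads[m] = tuple(blocks)
    n_dense = cfg["n_dense"]
    dmoves = [cfg[f"dense.dir{j}"] for j in range(n_dense - 1)]
    dense = tuple(_walk_chain(cfg["dense.start"], dmoves, space.dense_choices))
    spec = ArchSpec(heads=heads, dense_units=dense,
                    learning_rate=cfg["learning_rate"],
                    batch_size=cfg["batch_size"])
    return spec.validate()


def sample_spec(space: SearchSpace, rng: np.random.Generator,
                modalities: tuple[str, ...] = ("robot",)) -> ArchSpec:
    """Random valid ArchSpec; every legal structure is reachable."""
    return config_to_spec(sample_config(space, rng, modalities), space, modalities)


# ---------------------------------------------------------------------------
# TPE proposer
# ---------------------------------------------------------------------------

class TPESampler:
    """Categorical TPE over the conditional configuration space."""

    def __init__(self, space: SearchSpace, modalities: tuple[str, ...],
                 rng: np.random.Generator, gamma: float = 0.25,
                 n_startup: int = 10, n_candidates: int = 24):
        self.space = space
        self.modalities = modalities
        self.rng = rng
        self.gamma = gamma
        self.n_startup = n_startup
        self.n_candidates = n_candidates

    def _density(self, trials: list[dict], key: str) -> dict:
        """Laplace-smoothed categorical density over a dimension's domain,
        counting only trials where the dimension was active."""
        domain = _dimension_domain(key, self.space)
        counts = {v: 1.0 for v in domain}
        for cfg in trials:
            if key in cfg:
                counts[cfg[key]] += 1.0
        total = sum(counts.values())
        return {v: c / total for v, c in counts.items()}

    def propose(self, history: list[tuple[dict, float]]) -> dict:
        finite = [(c, y) for c, y in history if math.isfinite(y)]
        if len(finite) < self.n_startup:
            return sample_config(self.space, self.rng, self.modalities)
        finite.sort(key=lambda t: -t[1])
        n_good = max(1, math.ceil(self.gamma * len(finite)))
        good = [c for c, _ in finite[:n_good]]
        bad = [c for c, _ in finite[n_good:]] or good

        l_cache: dict[str, dict] = {}
        g_cache: dict[str, dict] = {}

        def dens(cache, trials, key):
            if key not in cache:
                cache[key] = self._density(trials, key)
            return cache[key]

        best_cfg, best_score = None, -np.inf
        for _ in range(self.n_candidates):
            cfg = self._sample_from(good, l_cache)
            score = 0.0
            for key, val in cfg.items():
                score += math.log(dens(l_cache, good, key)[val])
                score -= math.log(dens(g_cache, bad, key)[val])
            if score > best_score:
                best_cfg, best_score = cfg, score
        return best_cfg

    def _sample_from(self, good: list[dict], cache: dict[str, dict] | None = None) -> dict:
        """Sample a full conditional config with per-dimension densities
        fitted on the good trials."""
        cache = {} if cache is None else cache

        def pick(key):
            if key not in cache:
                cache[key] = self._density(good, key)
            dens = cache[key]
            vals = list(dens)
            probs = np.array([dens[v] for v in vals])
            return vals[self.rng.choice(len(vals), p=probs / probs.sum())]

        cfg: dict = {}
        for m in self.modalities:
            n_blocks = pick(f"{m}.n_blocks")
            cfg[f"{m}.n_blocks"] = n_blocks
            total = 0
            for b in range(n_blocks):
                cfg[f"{m}.block{b}.n_convs"] = pick(f"{m}.block{b}.n_convs")
                cfg[f"{m}.block{b}.pooling"] = pick(f"{m}.block{b}.pooling")
                total += cfg[f"{m}.block{b}.n_convs"]
            cfg[f"{m}.filters.start"] = pick(f"{m}.filters.start")
            for j in range(total - 1):
                cfg[f"{m}.filters.dir{j}"] = pick(f"{m}.filters.dir{j}")
        n_dense = pick("n_dense")
        cfg["n_dense"] = n_dense
        cfg["dense.start"] = pick("dense.start")
        for j in range(n_dense - 1):
            cfg[f"dense.dir{j}"] = pick(f"dense.dir{j}")
        cfg["learning_rate"] = pick("learning_rate")
        cfg["batch_size"] = pick("batch_size")
        return cfg


# ---------------------------------------------------------------------------
# Search driver
# ---------------------------------------------------------------------------

def run_search(space: SearchSpace, objective, max_evals: int = 50, seed: int = 0,
               algo: str = "tpe", modalities: tuple[str, ...] = ("robot",),
               log_path: str | Path | None = None,
               ) -> tuple[TrialResult, list[TrialResult]]:
    """Evaluate exactly ``max_evals`` sampled points and return the best.

    ``objective`` maps an ArchSpec to a score ``y`` or a ``(y, val_loss)``
    pair.  A raising objective records a failed trial with y = -inf and the
    search continues.  Best = argmax y, ties broken by lower validation loss
    and then by lower trial index.
    """
    if algo not in ("tpe", "random"):
        raise ValueError(f"unknown algo {algo!r}")
    rng = np.random.default_rng(seed)
    sampler = TPESampler(space, modalities, rng) if algo == "tpe" else None
    history: list[tuple[dict, float]] = []
    trials: list[TrialResult] = []
    for i in range(max_evals):
        cfg = (sampler.propose(history) if sampler
               else sample_config(space, rng, modalities))
        spec = config_to_spec(cfg, space, modalities)
        try:
            out = objective(spec)
            y, val_loss = out if isinstance(out, tuple) else (out, np.nan)
            if not math.isfinite(float(y)):
                raise ValueError(f"objective returned non-finite score {y!r}")
            trial = TrialResult(config=cfg, spec=spec.to_dict(), y=float(y),
                                val_loss=float(val_loss), trial_index=i, seed=seed)
        except Exception as exc:  # failed trial, search continues
            logger.warning("trial %d failed: %s", i, exc)
            trial = TrialResult(config=cfg, spec=spec.to_dict(), y=-np.inf,
                                val_loss=np.inf, trial_index=i, seed=seed,
                                status="failed", error=str(exc))
        trials.append(trial)
        history.append((cfg, trial.y))
    if log_path is not None:
        Path(log_path).write_text(
            "\n".join(t.to_json_line() for t in trials) + "\n")
    best = min(trials, key=lambda t: (-t.y,
                                      t.val_loss if math.isfinite(t.val_loss) else np.inf,
                                      t.trial_index))
    return best, trials


def objective_eval(spec: ArchSpec, train_data, val_data, epochs: int = 20,
                   seed: int = 0) -> tuple[float, float]:
    """Train a family instance for the trial budget and score it on the
    validation split: (macro F-measure, final validation loss).

    A spec that cannot be built for the given window shapes (temporal
    collapse) raises, which ``run_search`` records as a failed trial.
    """
    x, y = to_arrays(train_data)
    shapes = ({m: xi.shape[1:] for m, xi in x.items()} if isinstance(x, dict)
              else {next(iter(spec.heads)): x.shape[1:]})
    model = build_from_spec(spec, shapes, rng=np.random.default_rng(seed))
    xv, yv = to_arrays(val_data)
    hist = fit(model, x, y, x_val=xv, y_val=yv, epochs=epochs,
               batch_size=spec.batch_size, lr=spec.learning_rate,
               rng=np.random.default_rng(seed + 1))
    report = evaluate_model(model, val_data)
    return report.f_measure_macro, hist["val_loss"][-1]
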