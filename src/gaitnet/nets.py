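"""The constrained single/multi-head CNN family and the benchmark networks.

The family is a structural search space, not a single net: 1-3 blocks per
head, each block 1-3 convolutions (kernel 3, stride 1, same padding, each
followed by batch-norm and ReLU) closed by a size-2 max- or average-pool;
then 1-3 dense layers.  Filter counts come from {16, 32, 64, 128} and dense
widths from {32, 64, 128, 256, 512}, with *adjacent parameterized layers
differing by exactly a factor of two* (equality at a block boundary only if
explicitly allowed).  A multi-head instance runs one such stack per input
modality and concatenates the flattened head outputs before the shared dense
stack; a softmax layer over the five locomotion classes closes every net.

Three benchmark architectures are provided with exact parameter accounting:

* DeepConvLSTM - four 64-filter kernel-5 convolutions, two 128-unit LSTM
  layers, softmax; no batch-norm, so its non-trainable count is 0.
* LSTM-CNN - L(32)-L(32)-C(64,k5)-maxpool(2)-C(128,k3)-GAP-BN-softmax; the
  single batch-norm on the 128-wide GAP output carries the 256 non-trainable
  parameters.
* DDLMI - four conv+ReLU+max-pool stages, one dense layer followed by
  batch-norm and dropout, then softmax.  Its internals are config-driven;
  the default dense width of 288 gives the published 576 non-trainable
  parameters.

Dual-head variants cut each single-modality branch before its classifier,
concatenate, and add one softmax layer on the concatenation.

Closed-form parameter rules used throughout: conv1d k*c_in*f + f; dense
n_in*n_out + n_out; batch-norm on c channels 2c trainable + 2c
non-trainable; LSTM with input d and u units 4*((d+u)*u + u); pooling,
flatten, activations and dropout contribute nothing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    AvgPool1D, BatchNorm, Conv1D, Dense, Dropout, Flatten, GlobalAvgPool1D,
    LSTM, MaxPool1D, Network, ParamCount, ReLU,
)

N_CLASSES = 5
FILTER_CHOICES = (16, 32, 64, 128)
DENSE_CHOICES = (32, 64, 128, 256, 512)
LEARNING_RATE_CHOICES = (1e-4, 1e-3)
BATCH_SIZE_CHOICES = (32, 64, 128, 256)


class SpecValidationError(ValueError):
    pass


class TemporalCollapseError(ValueError):
    """Pooling or valid convolution would shrink the time axis below one step."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockSpec:
    """One block: 1-3 same-padding kernel-3 convolutions, then a pool of 2."""

    filters: tuple[int, ...]
    pooling: str = "max"

    def __post_init__(self) -> None:
        object.__setattr__(self, "filters", tuple(int(f) for f in self.filters))


@dataclass(frozen=True)
class ArchSpec:
    """A point in the constrained architecture space."""

    heads: dict[str, tuple[ConvBlockSpec, ...]]
    dense_units: tuple[int, ...]
    n_classes: int = N_CLASSES
    learning_rate: float = 1e-4
    batch_size: int = 32
    dense_batch_norm: bool = False
    allow_equal_at_boundary: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "heads",
                           {m: tuple(blocks) for m, blocks in self.heads.items()})
        object.__setattr__(self, "dense_units",
                           tuple(int(u) for u in self.dense_units))

    # -- validation -------------------------------------------------------
    def validate(self) -> "ArchSpec":
        if not self.heads:
            raise SpecValidationError("spec needs at least one head")
        for modality, blocks in self.heads.items():
            if not 1 <= len(blocks) <= 3:
                raise SpecValidationError(f"{modality}: blocks must number 1-3")
            boundary_after = set()
            chain: list[int] = []
            for b in blocks:
                if not 1 <= len(b.filters) <= 3:
                    raise SpecValidationError(f"{modality}: 1-3 convs per block")
                if b.pooling not in ("max", "average"):
                    raise SpecValidationError(f"unknown pooling {b.pooling!r}")
                if any(f not in FILTER_CHOICES for f in b.filters):
                    raise SpecValidationError(
                        f"{modality}: filters must come from {FILTER_CHOICES}")
                chain.extend(b.filters)
                boundary_after.add(len(chain) - 1)
            for i in range(len(chain) - 1):
                ratio = chain[i + 1] / chain[i]
                at_boundary = i in boundary_after
                if ratio in (2.0, 0.5):
                    continue
                if ratio == 1.0 and at_boundary and self.allow_equal_at_boundary:
                    continue
                raise SpecValidationError(
                    f"{modality}: filters {chain[i]}->{chain[i + 1]} violate "
                    "twofold adjacency")
        if not 1 <= len(self.dense_units) <= 3:
            raise SpecValidationError("dense stack must have 1-3 layers")
        if any(u not in DENSE_CHOICES for u in self.dense_units):
            raise SpecValidationError(f"dense units must come from {DENSE_CHOICES}")
        for a, b in zip(self.dense_units, self.dense_units[1:]):
            if b / a not in (2.0, 0.5):
                raise SpecValidationError(
                    f"dense units {a}->{b} violate twofold adjacency")
        if self.learning_rate not in LEARNING_RATE_CHOICES:
            raise SpecValidationError(f"learning rate must be one of {LEARNING_RATE_CHOICES}")
        if self.batch_size not in BATCH_SIZE_CHOICES:
            raise SpecValidationError(f"batch size must be one of {BATCH_SIZE_CHOICES}")
        return self

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "heads": {m: [{"filters": list(b.filters), "pooling": b.pooling}
                          for b in blocks]
                      for m, blocks in self.heads.items()},
            "dense_units": list(self.dense_units),
            "n_classes": self.n_classes,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "dense_batch_norm": self.dense_batch_norm,
            "allow_equal_at_boundary": self.allow_equal_at_boundary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        return cls(
            heads={m: tuple(ConvBlockSpec(tuple(b["filters"]), b["pooling"])
                            for b in blocks)
                   for m, blocks in d["heads"].items()},
            dense_units=tuple(d["dense_units"]),
            n_classes=d.get("n_classes", N_CLASSES),
            learning_rate=d.get("learning_rate", 1e-4),
            batch_size=d.get("batch_size", 32),
            dense_batch_norm=d.get("dense_batch_norm", False),
            allow_equal_at_boundary=d.get("allow_equal_at_boundary", False),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArchSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Reference instances of the family.  The published text pins the block and
# dense structure (EMG: 3 blocks x 2 convs, one 512 dense; robot: 3 blocks x
# 2 convs, dense 128 then 256; two-head: 2 blocks x 1 conv + 2 blocks x 3
# convs, one dense layer); the per-layer filter counts are this package's
# choice of ascending twofold chains within those structures.
EMG_REFERENCE_SPEC = ArchSpec(
    heads={"emg": (ConvBlockSpec((16, 32)), ConvBlockSpec((64, 128)),
                   ConvBlockSpec((64, 128)))},
    dense_units=(512,), learning_rate=1e-4, batch_size=128)

ROBOT_REFERENCE_SPEC = ArchSpec(
    heads={"robot": (ConvBlockSpec((16, 32)), ConvBlockSpec((64, 128)),
                     ConvBlockSpec((64, 128)))},
    dense_units=(128, 256), learning_rate=1e-4, batch_size=32)

MULTIHEAD_REFERENCE_SPEC = ArchSpec(
    heads={
        "emg": (ConvBlockSpec((16,)), ConvBlockSpec((32,))),
        "robot": (ConvBlockSpec((16, 32, 64)), ConvBlockSpec((128, 64, 32))),
    },
    dense_units=(128,), learning_rate=1e-4, batch_size=128)

REFERENCE_SPECS = {
    "emg_reference": EMG_REFERENCE_SPEC,
    "robot_reference": ROBOT_REFERENCE_SPEC,
    "multihead_reference": MULTIHEAD_REFERENCE_SPEC,
}


# ---------------------------------------------------------------------------
# Closed-form accounting
# ---------------------------------------------------------------------------

def conv1d_params(kernel: int, c_in: int, filters: int) -> int:
    return kernel * c_in * filters + filters


def dense_params(n_in: int, n_out: int) -> int:
    return n_in * n_out + n_out


def lstm_params(d: int, units: int) -> int:
    return 4 * ((d + units) * units + units)


def batchnorm_params(channels: int) -> tuple[int, int]:
    """(trainable, non_trainable)."""
    return 2 * channels, 2 * channels


def _head_output_width(blocks: tuple[ConvBlockSpec, ...], input_shape: tuple[int, int],
                       ) -> tuple[int, int, int, int]:
    """(flatten_width, trainable, non_trainable, final_T) for one head."""
    t, c = input_shape
    trainable = 0
    non_trainable = 0
    for block in blocks:
        for f in block.filters:
            trainable += conv1d_params(3, c, f)
            bt, bn = batchnorm_params(f)
            trainable += bt
            non_trainable += bn
            c = f
        t = t // 2
        if t < 1:
            raise TemporalCollapseError("pooling shrank the time axis below 1")
    return t * c, trainable, non_trainable, t


def family_param_count(spec: ArchSpec, input_shapes: dict[str, tuple[int, int]],
                       ) -> ParamCount:
    """Closed-form parameter count of a family instance, no model built."""
    spec.validate()
    trainable = 0
    non_trainable = 0
    widths = []
    for modality, blocks in spec.heads.items():
        w, tr, ntr, _ = _head_output_width(blocks, input_shapes[modality])
        widths.append(w)
        trainable += tr
        non_trainable += ntr
    n_in = sum(widths)
    for units in spec.dense_units:
        trainable += dense_params(n_in, units)
        if spec.dense_batch_norm:
            bt, bn = batchnorm_params(units)
            trainable += bt
            non_trainable += bn
        n_in = units
    trainable += dense_params(n_in, spec.n_classes)
    return ParamCount(trainable, non_trainable)


def count_parameters(model: Network) -> ParamCount:
    """Parameter count of a built model, from its weight arrays."""
    return model.param_count()


# ---------------------------------------------------------------------------
# Family builders
# ---------------------------------------------------------------------------

def _build_head(blocks: tuple[ConvBlockSpec, ...], input_shape: tuple[int, int],
                rng: np.random.Generator) -> list:
    t, c = input_shape
    layers: list = []
    for block in blocks:
        for f in block.filters:
            layers += [Conv1D(c, f, kernel_size=3, padding="same", rng=rng),
                       BatchNorm(f), ReLU()]
            c = f
        layers.append(MaxPool1D() if block.pooling == "max" else AvgPool1D())
        t = t // 2
        if t < 1:
            raise TemporalCollapseError("pooling shrank the time axis below 1")
    layers.append(Flatten())
    return layers


def _build_trunk(spec: ArchSpec, n_in: int, rng: np.random.Generator) -> list:
    layers: list = []
    for units in spec.dense_units:
        layers += [Dense(n_in, units, rng=rng)]
        if spec.dense_batch_norm:
            layers.append(BatchNorm(units))
        layers.append(ReLU())
        n_in = units
    layers.append(Dense(n_in, spec.n_classes, rng=rng))
    return layers


def build_single_head(spec: ArchSpec, input_shape: tuple[int, int],
                      rng: np.random.Generator | None = None) -> Network:
    """Family instance with one head; softmax over the class logits."""
    spec.validate()
    if len(spec.heads) != 1:
        raise SpecValidationError("single-head builder needs exactly one head")
    rng = rng or np.random.default_rng(0)
    modality, blocks = next(iter(spec.heads.items()))
    head = _build_head(blocks, input_shape, rng)
    width, _, _, _ = _head_output_width(blocks, input_shape)
    trunk = _build_trunk(spec, width, rng)
    return Network(heads=[(modality, head)], trunk=trunk, n_classes=spec.n_classes)


def build_multi_head(spec: ArchSpec, input_shapes: dict[str, tuple[int, int]],
                     rng: np.random.Generator | None = None) -> Network:
    """Family instance with one head per modality, concatenated before the
    dense stack."""
    spec.validate()
    if len(spec.heads) < 2:
        raise SpecValidationError("multi-head builder needs >= 2 heads")
    rng = rng or np.random.default_rng(0)
    heads = []
    total_width = 0
    for modality, blocks in spec.heads.items():
        heads.append((modality, _build_head(blocks, input_shapes[modality], rng)))
        width, _, _, _ = _head_output_width(blocks, input_shapes[modality])
        total_width += width
    trunk = _build_trunk(spec, total_width, rng)
    return Network(heads=heads, trunk=trunk, n_classes=spec.n_classes)


def build_from_spec(spec: ArchSpec, input_shapes: dict[str, tuple[int, int]],
                    rng: np.random.Generator | None = None) -> Network:
    if len(spec.heads) == 1:
        modality = next(iter(spec.heads))
        return build_single_head(spec, input_shapes[modality], rng=rng)
    return build_multi_head(spec, input_shapes, rng=rng)


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

def _deepconvlstm_branch(input_shape: tuple[int, int],
                         rng: np.random.Generator) -> tuple[list, int]:
    t, c = input_shape
    if t < 17:
        raise TemporalCollapseError("DeepConvLSTM needs >= 17 timesteps")
    layers: list = []
    for _ in range(4):
        layers += [Conv1D(c, 64, kernel_size=5, padding="valid", rng=rng), ReLU()]
        c = 64
        t -= 4
    layers += [LSTM(64, 128, return_sequences=True, rng=rng),
               LSTM(128, 128, return_sequences=False, rng=rng)]
    return layers, 128


def build_deepconvlstm(input_shape: tuple[int, int], n_classes: int = N_CLASSES,
                       rng: np.random.Generator | None = None) -> Network:
    """Four kernel-5 valid convolutions (64 filters), two 128-unit LSTMs,
    softmax; no batch normalization."""
    rng = rng or np.random.default_rng(0)
    branch, width = _deepconvlstm_branch(input_shape, rng)
    return Network(heads=[("input", branch)],
                   trunk=[Dense(width, n_classes, rng=rng)], n_classes=n_classes)


def _lstm_cnn_branch(input_shape: tuple[int, int],
                     rng: np.random.Generator) -> tuple[list, int]:
    t, c = input_shape
    if ((t - 4) // 2) < 3:
        raise TemporalCollapseError("LSTM-CNN needs conv(5) -> pool(2) -> conv(3) to fit")
    layers: list = [
        LSTM(c, 32, return_sequences=True, rng=rng),
        LSTM(32, 32, return_sequences=True, rng=rng),
        Conv1D(32, 64, kernel_size=5, padding="valid", rng=rng), ReLU(),
        MaxPool1D(),
        Conv1D(64, 128, kernel_size=3, padding="valid", rng=rng), ReLU(),
        GlobalAvgPool1D(),
        BatchNorm(128),
    ]
    return layers, 128


def build_lstm_cnn(input_shape: tuple[int, int], n_classes: int = N_CLASSES,
                   rng: np.random.Generator | None = None) -> Network:
    """L(32)-L(32)-C(64,k5)-maxpool(2)-C(128,k3)-GAP-BN-softmax."""
    rng = rng or np.random.default_rng(0)
    branch, width = _lstm_cnn_branch(input_shape, rng)
    return Network(heads=[("input", branch)],
                   trunk=[Dense(width, n_classes, rng=rng)], n_classes=n_classes)


@dataclass(frozen=True)
class DDLMIConfig:
    """DDLMI internals are not fully pinned by its published description;
    these defaults respect it (4 conv/pool stages, one dense layer followed
    by batch-norm and dropout) and give the published 576 non-trainable
    parameters via the 288-unit dense width."""

    filters: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel_size: int = 5
    dense_units: int = 288
    dropout_rate: float = 0.5


def _ddlmi_branch(input_shape: tuple[int, int], config: DDLMIConfig,
                  rng: np.random.Generator) -> tuple[list, int]:
    t, c = input_shape
    layers: list = []
    for f in config.filters:
        t = t - config.kernel_size + 1
        if t < 2:
            raise TemporalCollapseError("DDLMI conv/pool stack does not fit")
        layers += [Conv1D(c, f, kernel_size=config.kernel_size, padding="valid",
                          rng=rng), ReLU(), MaxPool1D()]
        t //= 2
        c = f
    layers += [Flatten(), Dense(t * c, config.dense_units, rng=rng), ReLU(),
               BatchNorm(config.dense_units), Dropout(config.dropout_rate, rng=rng)]
    return layers, config.dense_units


def build_ddlmi(input_shape: tuple[int, int], config: DDLMIConfig = DDLMIConfig(),
                n_classes: int = N_CLASSES,
                rng: np.random.Generator | None = None) -> Network:
    """Four conv+ReLU+max-pool stages, dense -> batch-norm -> dropout, softmax."""
    rng = rng or np.random.default_rng(0)
    branch, width = _ddlmi_branch(input_shape, config, rng)
    return Network(heads=[("input", branch)],
                   trunk=[Dense(width, n_classes, rng=rng)], n_classes=n_classes)


_BRANCH_BUILDERS = {
    "deepconvlstm": lambda shape, rng: _deepconvlstm_branch(shape, rng),
    "lstm_cnn": lambda shape, rng: _lstm_cnn_branch(shape, rng),
    "ddlmi": lambda shape, rng: _ddlmi_branch(shape, DDLMIConfig(), rng),
}


def build_dual_head_variant(base: str, input_shapes: dict[str, tuple[int, int]],
                            n_classes: int = N_CLASSES,
                            rng: np.random.Generator | None = None) -> Network:
    """Two-head variant of a benchmark: one full single-modality branch per
    input, truncated before its classifier; branch outputs concatenated and
    topped with a single softmax layer."""
    if base not in _BRANCH_BUILDERS:
        raise ValueError(f"unknown benchmark {base!r}; choose from {sorted(_BRANCH_BUILDERS)}")
    if len(input_shapes) != 2:
        raise ValueError("dual-head variants take exactly two modalities")
    rng = rng or np.random.default_rng(0)
    heads = []
    total = 0
    for modality, shape in input_shapes.items():
        branch, width = _BRANCH_BUILDERS[base](shape, rng)
        heads.append((modality, branch))
        total += width
    return Network(heads=heads, trunk=[Dense(total, n_classes, rng=rng)],
                   n_classes=n_classes)


BENCHMARK_BUILDERS = {
    "deepconvlstm": build_deepconvlstm,
    "lstm_cnn": build_lstm_cnn,
    "ddlmi": build_ddlmi,
}


# ---------------------------------------------------------------------------
# Constraint-satisfaction helper
# ---------------------------------------------------------------------------

def iter_single_head_specs(modality: str = "emg", dense_batch_norm: bool = False):
    """Enumerate every single-head family spec (structure only: filters,
    blocks, dense stack) under strict twofold adjacency."""
    def chains(choices, length):
        if length == 0:
            yield ()
            return
        for start in choices:
            chain = [start]
            yield from _extend(chain, choices, length)

    def _extend(chain, choices, length):
        if len(chain) == length:
            yield tuple(chain)
            return
        for nxt in (chain[-1] * 2, chain[-1] // 2):
            if nxt in choices:
                yield from _extend(chain + [nxt], choices, length)

    for n_blocks in (1, 2, 3):
        for convs in _product_lengths(n_blocks):
            total = sum(convs)
            for chain in chains(FILTER_CHOICES, total):
                blocks = []
                i = 0
                for c in convs:
                    blocks.append(ConvBlockSpec(chain[i:i + c]))
                    i += c
                for n_dense in (1, 2, 3):
                    for dchain in chains(DENSE_CHOICES, n_dense):
                        yield ArchSpec(heads={modality: tuple(blocks)},
                                       dense_units=dchain,
                                       dense_batch_norm=dense_batch_norm)


def _product_lengths(n_blocks: int):
    if n_blocks == 1:
        for a in (1, 2, 3):
            yield (a,)
    else:
        for a in (1, 2, 3):
            for rest in _product_lengths(n_blocks - 1):
                yield (a,) + rest


def solve_family_spec(target_trainable: int, target_non_trainable: int,
                      input_shape: tuple[int, int], modality: str = "emg",
                      max_solutions: int = 10) -> list[ArchSpec]:
    """Search the single-head space for specs whose closed-form counts match
    the given totals exactly (with and without dense batch-norm).

    A constraint-satisfaction aid for published parameter totals whose
    per-layer structure is not stated; exhaustive over the discrete space.
    """
    solutions: list[ArchSpec] = []
    for dense_bn in (False, True):
        for spec in iter_single_head_specs(modality, dense_batch_norm=dense_bn):
            try:
                pc = family_param_count(spec, {modality: input_shape})
            except TemporalCollapseError:
                continue
            if pc.trainable == target_trainable and pc.non_trainable == target_non_trainable:
                solutions.append(spec)
                if len(solutions) >= max_solutions:
                    return solutions
    return solutions
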