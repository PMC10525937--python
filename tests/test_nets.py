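"""Architecture-family constraints and exact parameter accounting."""

from __future__ import annotations

import numpy as np
import pytest

from gaitnet.nets import (
    ArchSpec, ConvBlockSpec, DDLMIConfig, EMG_REFERENCE_SPEC,
    MULTIHEAD_REFERENCE_SPEC, ROBOT_REFERENCE_SPEC, SpecValidationError,
    TemporalCollapseError, build_ddlmi, build_deepconvlstm,
    build_dual_head_variant, build_from_spec, build_lstm_cnn,
    build_multi_head, build_single_head, conv1d_params, count_parameters,
    dense_params, family_param_count, lstm_params, solve_family_spec,
)

EMG_SHAPE = (3520, 8)
ROBOT_SHAPE = (125, 7)


class TestSpecValidation:
    def test_reference_specs_are_valid(self):
        for spec in (EMG_REFERENCE_SPEC, ROBOT_REFERENCE_SPEC,
                     MULTIHEAD_REFERENCE_SPEC):
            spec.validate()

    @pytest.mark.parametrize("bad", [
        # filter outside the allowed set
        ArchSpec(heads={"robot": (ConvBlockSpec((48,)),)}, dense_units=(128,)),
        # adjacency violated within a block
        ArchSpec(heads={"robot": (ConvBlockSpec((16, 64)),)}, dense_units=(128,)),
        # equal filters at a block boundary without the config flag
        ArchSpec(heads={"robot": (ConvBlockSpec((16, 32)), ConvBlockSpec((32,)))},
                 dense_units=(128,)),
        # too many convs in one block
        ArchSpec(heads={"robot": (ConvBlockSpec((16, 32, 64, 128)),)},
                 dense_units=(128,)),
        # dense adjacency violated
        ArchSpec(heads={"robot": (ConvBlockSpec((16,)),)}, dense_units=(32, 128)),
        # dense width outside the set
        ArchSpec(heads={"robot": (ConvBlockSpec((16,)),)}, dense_units=(100,)),
        # learning rate outside the space
        ArchSpec(heads={"robot": (ConvBlockSpec((16,)),)}, dense_units=(128,),
                 learning_rate=5e-4),
        # batch size outside the space
        ArchSpec(heads={"robot": (ConvBlockSpec((16,)),)}, dense_units=(128,),
                 batch_size=48),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(SpecValidationError):
            bad.validate()

    def test_equal_boundary_allowed_with_flag(self):
        spec = ArchSpec(heads={"robot": (ConvBlockSpec((16, 32)),
                                         ConvBlockSpec((32,)))},
                        dense_units=(128,), allow_equal_at_boundary=True)
        spec.validate()

    def test_json_round_trip(self, tmp_path):
        ROBOT_REFERENCE_SPEC.to_json(tmp_path / "spec.json")
        back = ArchSpec.from_json(tmp_path / "spec.json")
        assert back == ROBOT_REFERENCE_SPEC


class TestFamilyBuilders:
    def test_robot_reference_builds_and_outputs_probabilities(self, rng):
        model = build_single_head(ROBOT_REFERENCE_SPEC, ROBOT_SHAPE, rng=rng)
        p = model.predict_proba(rng.normal(size=(4, *ROBOT_SHAPE)))
        assert p.shape == (4, 5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_emg_reference_accepts_emg_shape(self, rng):
        model = build_single_head(EMG_REFERENCE_SPEC, EMG_SHAPE, rng=rng)
        p = model.predict_proba(rng.normal(size=(2, *EMG_SHAPE)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_minimal_spec_on_tiny_input(self, rng):
        spec = ArchSpec(heads={"robot": (ConvBlockSpec((16,)),)}, dense_units=(32,))
        model = build_single_head(spec, (8, 2), rng=rng)
        p = model.predict_proba(rng.normal(size=(3, 8, 2)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_temporal_collapse_raises(self):
        spec = ArchSpec(heads={"robot": (ConvBlockSpec((16,)), ConvBlockSpec((32,)),
                                         ConvBlockSpec((64,)))}, dense_units=(32,))
        with pytest.raises(TemporalCollapseError):
            build_single_head(spec, (4, 7))

    def test_multihead_concat_width_is_sum_of_head_widths(self, rng):
        model = build_multi_head(MULTIHEAD_REFERENCE_SPEC,
                                 {"emg": EMG_SHAPE, "robot": ROBOT_SHAPE}, rng=rng)
        x = {"emg": rng.normal(size=(2, *EMG_SHAPE)),
             "robot": rng.normal(size=(2, *ROBOT_SHAPE))}
        model.forward(x)
        # EMG head: T 3520 -> 880 after two pools, 32 filters; robot: 125 -> 31, 32 filters
        assert model._head_widths == [880 * 32, 31 * 32]

    @pytest.mark.parametrize("spec,shapes", [
        (ROBOT_REFERENCE_SPEC, {"robot": ROBOT_SHAPE}),
        (EMG_REFERENCE_SPEC, {"emg": EMG_SHAPE}),
        (MULTIHEAD_REFERENCE_SPEC, {"emg": EMG_SHAPE, "robot": ROBOT_SHAPE}),
        (ArchSpec(heads={"robot": (ConvBlockSpec((128, 64), pooling="average"),)},
                  dense_units=(512, 256, 128), dense_batch_norm=True),
         {"robot": ROBOT_SHAPE}),
    ], ids=["robot_ref", "emg_ref", "multihead_ref", "avgpool_dense_bn"])
    def test_closed_form_count_equals_built_model(self, spec, shapes):
        built = count_parameters(build_from_spec(spec, shapes))
        closed = family_param_count(spec, shapes)
        assert built == closed

    def test_dropping_a_head_changes_count_by_closed_form_delta(self):
        """Removing one head removes its conv/BN parameters and its share of
        the first dense layer's input weights."""
        full = family_param_count(MULTIHEAD_REFERENCE_SPEC,
                                  {"emg": EMG_SHAPE, "robot": ROBOT_SHAPE})
        solo = ArchSpec(heads={"robot": MULTIHEAD_REFERENCE_SPEC.heads["robot"]},
                        dense_units=MULTIHEAD_REFERENCE_SPEC.dense_units)
        part = family_param_count(solo, {"robot": ROBOT_SHAPE})
        emg_width = 880 * 32
        dense0 = MULTIHEAD_REFERENCE_SPEC.dense_units[0]
        # conv weights + BN gamma/beta; BN moving stats are non-trainable
        emg_head_trainable = (conv1d_params(3, 8, 16) + 2 * 16
                              + conv1d_params(3, 16, 32) + 2 * 32)
        assert full.trainable - part.trainable == emg_head_trainable + emg_width * dense0
        assert full.non_trainable - part.non_trainable == 2 * 16 + 2 * 32


class TestBenchmarks:
    def test_deepconvlstm_channel_delta(self):
        a = count_parameters(build_deepconvlstm(EMG_SHAPE))
        b = count_parameters(build_deepconvlstm(ROBOT_SHAPE))
        assert a.trainable - b.trainable == 5 * 64  # first conv input weights
        assert a.non_trainable == b.non_trainable == 0

    def test_lstm_cnn_channel_delta(self):
        a = count_parameters(build_lstm_cnn(EMG_SHAPE))
        b = count_parameters(build_lstm_cnn(ROBOT_SHAPE))
        assert a.trainable - b.trainable == 4 * 32  # first LSTM input weights
        assert a.non_trainable == b.non_trainable == 256

    def test_deepconvlstm_closed_form(self):
        expected = (conv1d_params(5, 8, 64) + 3 * conv1d_params(5, 64, 64)
                    + lstm_params(64, 128) + lstm_params(128, 128)
                    + dense_params(128, 5))
        assert count_parameters(build_deepconvlstm(EMG_SHAPE)).trainable == expected

    def test_ddlmi_non_trainable_tracks_batch_norm_width(self):
        default = count_parameters(build_ddlmi(ROBOT_SHAPE))
        assert default.non_trainable == 2 * 288
        wide = count_parameters(build_ddlmi(ROBOT_SHAPE,
                                            DDLMIConfig(dense_units=100)))
        assert wide.non_trainable == 2 * 100

    def test_ddlmi_too_short_input(self):
        with pytest.raises(TemporalCollapseError):
            build_ddlmi((20, 7))

    def test_dual_head_count_is_branches_plus_merged_classifier(self):
        """dual trainable = branch1 + branch2 - two single classifiers
        + one classifier on the concatenation."""
        for base, build in (("deepconvlstm", build_deepconvlstm),
                            ("lstm_cnn", build_lstm_cnn)):
            single_e = count_parameters(build(EMG_SHAPE)).trainable
            single_r = count_parameters(build(ROBOT_SHAPE)).trainable
            dual = count_parameters(build_dual_head_variant(
                base, {"emg": EMG_SHAPE, "robot": ROBOT_SHAPE}))
            expected = (single_e - dense_params(128, 5)
                        + single_r - dense_params(128, 5)
                        + dense_params(256, 5))
            assert dual.trainable == expected

    def test_dual_head_requires_two_modalities(self):
        with pytest.raises(ValueError):
            build_dual_head_variant("lstm_cnn", {"emg": EMG_SHAPE})
        with pytest.raises(ValueError):
            build_dual_head_variant("nope", {"emg": EMG_SHAPE, "robot": ROBOT_SHAPE})

    def test_benchmark_outputs_are_probabilities(self, rng):
        model = build_lstm_cnn(ROBOT_SHAPE, rng=rng)
        p = model.predict_proba(rng.normal(size=(3, *ROBOT_SHAPE)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_solver_recovers_spec_with_matching_totals():
    """The constraint solver finds a spec reproducing a known instance's
    exact parameter totals."""
    target = ArchSpec(heads={"emg": (ConvBlockSpec((16, 32)),)},
                      dense_units=(64, 128))
    pc = family_param_count(target, {"emg": (64, 4)})
    found = solve_family_spec(pc.trainable, pc.non_trainable, (64, 4),
                              modality="emg", max_solutions=3)
    assert found
    for spec in found:
        got = family_param_count(spec, {"emg": (64, 4)})
        assert (got.trainable, got.non_trainable) == (pc.trainable, pc.non_trainable)
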