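"""Sequence I/O, preprocessing and channel-splitting behaviour."""

import numpy as np
import pytest

from soconvesn.data_model import (
    CHANNEL_DIM,
    KINECT20_MAP,
    PARTS,
    JointMap,
    SkeletonSequence,
    center_on_hips,
    load_dataset_hdf5,
    load_sequences,
    pad_channel_sets,
    preprocess_sequences,
    save_dataset_hdf5,
    smooth_savgol,
    split_channels,
)
from soconvesn.synthetic import SYNTH16_MAP, GeneratorConfig, default_class_specs, generate_action_dataset, generate_skeleton_sequences


class TestLoadSequences:
    def test_text_file_shape(self, tmp_path):
        rows = np.arange(40 * 60, dtype=float).reshape(40, 60)
        f = tmp_path / "seq.txt"
        np.savetxt(f, rows)
        (seq,) = load_sequences(f)
        assert seq.n_frames == 40 and seq.n_joints == 20

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text("")
        with pytest.raises(ValueError, match="no frames"):
            load_sequences(f)

    def test_column_count_must_be_multiple_of_three(self, tmp_path):
        f = tmp_path / "bad.txt"
        np.savetxt(f, np.ones((4, 59)))
        with pytest.raises(ValueError, match="J x 3"):
            load_sequences(f)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_sequences(tmp_path / "nope.csv")

    def test_hdf5_roundtrip_of_raw_sequences(self, tmp_path):
        import h5py

        seqs = generate_skeleton_sequences(
            GeneratorConfig(classes=default_class_specs(), samples_per_class=2, seed=0)
        )
        path = tmp_path / "raw.h5"
        with h5py.File(path, "w") as f:
            for i, s in enumerate(seqs):
                d = f.create_dataset(f"s{i:03d}", data=s.frames.reshape(s.n_frames, -1))
                d.attrs["label"] = s.label
        loaded = load_sequences(path)
        assert len(loaded) == len(seqs)
        np.testing.assert_allclose(loaded[0].frames, seqs[0].frames)


class TestCenterOnHips:
    def _seq(self, frames):
        return SkeletonSequence(frames=np.asarray(frames, dtype=float))

    def test_two_frame_hand_computed(self):
        # hips at joints 0,1,2; their mean over both frames is (1,0,0),
        # so every x coordinate drops by exactly 1
        frames = np.zeros((2, 4, 3))
        frames[:, 0] = [1, 0, 0]
        frames[:, 1] = [2, 0, 0]
        frames[:, 2] = [0, 0, 0]
        frames[:, 3] = [5, 5, 5]
        centered = center_on_hips(self._seq(frames), _StubMap((0, 1, 2)))
        assert np.allclose(centered.frames[:, 3], [[4, 5, 5], [4, 5, 5]])
        assert np.allclose(centered.frames[:, 1], [[1, 0, 0], [1, 0, 0]])

    def test_translation_invariance_and_idempotence(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(5, 16, 3))
        jm = SYNTH16_MAP
        base = center_on_hips(self._seq(frames), jm)
        shifted = center_on_hips(self._seq(frames + np.array([5.0, 5.0, 5.0])), jm)
        np.testing.assert_allclose(shifted.frames, base.frames, atol=1e-12)
        twice = center_on_hips(base, jm)
        np.testing.assert_allclose(twice.frames, base.frames, atol=1e-12)

    def test_hip_joint_out_of_range(self):
        with pytest.raises(IndexError):
            center_on_hips(self._seq(np.zeros((2, 3, 3))), _StubMap((0, 1, 9)))


class _StubMap:
    """Minimal stand-in exposing only hip_joints (for centring tests)."""

    def __init__(self, hips):
        self.hip_joints = hips


class TestSavgol:
    def _traj(self, values):
        T = len(values)
        frames = np.zeros((T, 1, 3))
        frames[:, 0, 0] = values
        return SkeletonSequence(frames=frames)

    def test_low_order_polynomial_unchanged(self):
        t = np.arange(20, dtype=float)
        seq = self._traj(0.5 * t**2 - t + 3)
        out = smooth_savgol(seq, window=5, polyorder=2)
        np.testing.assert_allclose(out.frames, seq.frames, atol=1e-9)

    def test_constant_unchanged(self):
        seq = self._traj(np.full(10, 2.5))
        out = smooth_savgol(seq, window=5, polyorder=2)
        np.testing.assert_allclose(out.frames, seq.frames, atol=1e-12)

    def test_matches_sliding_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        T, w, order = 30, 5, 2
        y = np.sin(0.3 * np.arange(T)) + 0.1 * rng.normal(size=T)
        out = smooth_savgol(self._traj(y), window=w, polyorder=order).frames[:, 0, 0]
        half = w // 2
        # oracle: centred least-squares polynomial fit per window
        for i in range(half, T - half):
            x = np.arange(-half, half + 1, dtype=float)
            coeffs = np.polynomial.polynomial.polyfit(x, y[i - half : i + half + 1], order)
            assert abs(out[i] - coeffs[0]) < 1e-9

    def test_too_short_sequence(self):
        with pytest.raises(ValueError, match="window"):
            smooth_savgol(self._traj(np.ones(3)), window=5, polyorder=2)


class TestPadding:
    def test_pad_appends_zero_rows_and_keeps_prefix(self, action_dataset):
        ds = generate_action_dataset(
            GeneratorConfig(classes=default_class_specs(), samples_per_class=3, seed=4)
        )
        assert ds.padded_length == max(ds.lengths)
        for i, cs in enumerate(ds.channel_sets):
            T = ds.lengths[i]
            for ch in cs.values():
                assert ch.series.shape == (ds.padded_length, CHANNEL_DIM)
                assert np.abs(ch.series[T:]).sum() == 0.0

    def test_equal_lengths_identity(self):
        from soconvesn.data_model import BodyPartChannel

        cs = [{p: BodyPartChannel(part=p, series=np.ones((7, 9))) for p in PARTS}]
        ds = pad_channel_sets(cs, ["a"], target_T=7)
        np.testing.assert_array_equal(ds.channel_sets[0]["CT"].series, np.ones((7, 9)))

    def test_target_smaller_than_longest_rejected(self):
        from soconvesn.data_model import BodyPartChannel

        cs = [{p: BodyPartChannel(part=p, series=np.ones((9, 9))) for p in PARTS}]
        with pytest.raises(ValueError, match="target_T"):
            pad_channel_sets(cs, ["a"], target_T=5)


class TestSplitChannels:
    def test_channels_are_t_by_nine(self):
        seqs = generate_skeleton_sequences(
            GeneratorConfig(classes=default_class_specs(), samples_per_class=1, seed=0)
        )
        channels = split_channels(seqs[0], SYNTH16_MAP)
        for part in PARTS:
            assert channels[part].series.shape == (seqs[0].n_frames, 9)

    def test_partition_roundtrip(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(6, 20, 3))
        seq = SkeletonSequence(frames=frames)
        channels = split_channels(seq, KINECT20_MAP)
        rebuilt = np.full_like(frames, np.nan)
        for part in PARTS:
            joints = KINECT20_MAP.part_to_joints[part]
            rebuilt[:, list(joints)] = channels[part].series.reshape(6, 3, 3)
        for j in KINECT20_MAP.discarded:
            rebuilt[:, j] = frames[:, j]
        np.testing.assert_array_equal(rebuilt, frames)
        # every used joint in exactly one channel
        used = KINECT20_MAP.used_joints
        assert len(used) == len(set(used)) == 15

    def test_overlapping_parts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            JointMap(
                part_to_joints={
                    "LA": (0, 1, 2),
                    "RA": (2, 3, 4),
                    "CT": (5, 6, 7),
                    "LL": (8, 9, 10),
                    "RL": (11, 12, 13),
                },
                hip_joints=(0, 8, 11),
            )


def test_joint_map_json_roundtrip():
    jm = JointMap.from_json(KINECT20_MAP.to_json())
    assert jm.part_to_joints == KINECT20_MAP.part_to_joints
    assert jm.hip_joints == KINECT20_MAP.hip_joints


def test_dataset_hdf5_roundtrip(tmp_path, action_dataset):
    path = tmp_path / "ds.h5"
    save_dataset_hdf5(action_dataset, path)
    loaded = load_dataset_hdf5(path)
    assert loaded.labels == action_dataset.labels
    np.testing.assert_array_equal(
        loaded.channel_sets[0]["CT"].series, action_dataset.channel_sets[0]["CT"].series
    )


def test_preprocess_chain_on_raw_skeletons():
    seqs = generate_skeleton_sequences(
        GeneratorConfig(classes=default_class_specs(), samples_per_class=2, seed=9)
    )
    ds = preprocess_sequences(seqs, SYNTH16_MAP)
    assert len(ds) == 8
    assert all(cs["LA"].series.shape[1] == 9 for cs in ds.channel_sets)
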