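"""Skeleton sequence containers, I/O and preprocessing.

A skeleton action sample is a ``T x J x 3`` array of joint coordinates.
Before reservoir learning each sequence is (i) re-expressed in a
body-centred frame by subtracting the per-sequence mean of the three hip
joints, (ii) smoothed per coordinate with a Savitzky-Golay filter and
(iii) zero-padded to a common length.  The 15 used joints are then split
into five body-part channels (left/right arm, central trunk, left/right
leg), each a ``T x 9`` multivariate series that drives one reservoir.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import h5py
import numpy as np
from scipy.signal import savgol_filter

PARTS: Tuple[str, ...] = ("LA", "RA", "CT", "LL", "RL")
#: feature dimension of one body-part channel: 3 joints x (x, y, z)
CHANNEL_DIM = 9


@dataclass
class SkeletonSequence:
    """One recorded action: ``frames[t, j]`` is the 3-D position of joint *j*."""

    frames: np.ndarray  # T x J x 3
    frame_rate: Optional[float] = None
    label: Optional[str] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be T x J x 3, got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("no frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_joints(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class JointMap:
    """Assignment of skeleton joints to the five body-part channels.

    ``part_to_joints`` maps each part name to exactly three joint indices
    (so every channel carries 9 coordinate features).  ``hip_joints`` are
    the three joints (centre, left, right hip) whose mean defines the
    body-centred origin.  Joints in ``discarded`` (e.g. the head on
    20-joint skeletons) never enter any channel.
    """

    part_to_joints: Mapping[str, Tuple[int, int, int]]
    hip_joints: Tuple[int, int, int]
    discarded: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if set(self.part_to_joints) != set(PARTS):
            raise ValueError(f"parts must be exactly {PARTS}")
        seen: set = set()
        for part, joints in self.part_to_joints.items():
            if len(joints) != 3:
                raise ValueError(f"part {part} must list exactly 3 joints")
            if seen & set(joints):
                raise ValueError("overlapping part definitions")
            seen |= set(joints)

    @property
    def used_joints(self) -> List[int]:
        out: List[int] = []
        for part in PARTS:
            out.extend(self.part_to_joints[part])
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "part_to_joints": {p: list(j) for p, j in self.part_to_joints.items()},
                "hip_joints": list(self.hip_joints),
                "discarded": list(self.discarded),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "JointMap":
        obj = json.loads(text)
        return cls(
            part_to_joints={p: tuple(j) for p, j in obj["part_to_joints"].items()},
            hip_joints=tuple(obj["hip_joints"]),
            discarded=tuple(obj.get("discarded", ())),
        )


#: Kinect-style 20-joint skeleton (hip centre, spine, shoulder centre, head,
#: then left/right arm and leg chains).  The trunk keeps the three axial
#: joints; each limb keeps its three distal joints; head, shoulders and the
#: lateral hips are discarded so that every channel has 9 features.
KINECT20_MAP = JointMap(
    part_to_joints={
        "CT": (0, 1, 2),
        "LA": (5, 6, 7),
        "RA": (9, 10, 11),
        "LL": (13, 14, 15),
        "RL": (17, 18, 19),
    },
    hip_joints=(0, 12, 16),
    discarded=(3, 4, 8, 12, 16),
)

#: Florence-style 15-joint skeleton (head, neck, spine, then limb chains).
#: All 15 joints are used, three per part; the skeleton has no explicit hip
#: centre, so the spine stands in for it when centring.
FLORENCE15_MAP = JointMap(
    part_to_joints={
        "CT": (0, 1, 2),
        "LA": (3, 4, 5),
        "RA": (6, 7, 8),
        "LL": (9, 10, 11),
        "RL": (12, 13, 14),
    },
    hip_joints=(2, 9, 12),
    discarded=(),
)

DEFAULT_JOINT_MAPS: Dict[str, JointMap] = {
    "kinect20": KINECT20_MAP,
    "florence15": FLORENCE15_MAP,
}


@dataclass
class BodyPartChannel:
    """One body part's ``T x 9`` coordinate series; row *t* is u(t)."""

    part: str
    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.part not in PARTS:
            raise ValueError(f"unknown part {self.part!r}")
        if self.series.ndim != 2:
            raise ValueError("series must be 2-D")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("non-finite channel values")


ChannelSet = Dict[str, BodyPartChannel]


@dataclass
class LabeledDataset:
    """A set of five-channel samples with labels and an optional split."""

    channel_sets: List[ChannelSet]
    labels: List[str]
    padded_length: Optional[int] = None
    split: Optional[List[str]] = None  # per-sample: train/val/test
    lengths: Optional[List[int]] = None  # original (pre-padding) frame counts

    def __post_init__(self) -> None:
        if len(self.channel_sets) != len(self.labels):
            raise ValueError("labels and channel_sets length mismatch")

    def __len__(self) -> int:
        return len(self.channel_sets)

    @property
    def classes(self) -> List[str]:
        return sorted(set(self.labels))

    def subset(self, which: str) -> "LabeledDataset":
        if self.split is None:
            raise ValueError("dataset has no split")
        idx = [i for i, s in enumerate(self.split) if s == which]
        return LabeledDataset(
            channel_sets=[self.channel_sets[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            padded_length=self.padded_length,
            split=[which] * len(idx),
            lengths=[self.lengths[i] for i in idx] if self.lengths else None,
        )


def load_sequences(path, joint_map: Optional[JointMap] = None) -> List[SkeletonSequence]:
    """Load skeleton sequences from delimited text or an HDF5 container.

    Text files hold one sample: one frame per row, ``J*3`` columns
    (x1 y1 z1 x2 y2 z2 ...).  HDF5 containers hold one 2-D dataset per
    sample (same row layout) plus optional ``label``/``subject`` attrs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix in (".h5", ".hdf5"):
        seqs: List[SkeletonSequence] = []
        with h5py.File(path, "r") as f:
            for name in sorted(f.keys()):
                ds = f[name]
                seqs.append(
                    SkeletonSequence(
                        frames=_rows_to_frames(np.asarray(ds)),
                        label=ds.attrs.get("label"),
                        subject_id=ds.attrs.get("subject"),
                    )
                )
        if not seqs:
            raise ValueError("no frames")
        _check_consistent_j(seqs)
        return seqs
    rows = np.loadtxt(path, ndmin=2, delimiter=_sniff_delimiter(path))
    if rows.size == 0:
        raise ValueError("no frames")
    seqs = [SkeletonSequence(frames=_rows_to_frames(rows))]
    return seqs


def _sniff_delimiter(path: Path) -> Optional[str]:
    with open(path) as fh:
        first = fh.readline()
    return "," if "," in first else None


def _rows_to_frames(rows: np.ndarray) -> np.ndarray:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] % 3 != 0:
        raise ValueError(f"columns not J x 3 (got {rows.shape[1]})")
    return rows.reshape(rows.shape[0], rows.shape[1] // 3, 3)


def _check_consistent_j(seqs: Sequence[SkeletonSequence]) -> None:
    js = {s.n_joints for s in seqs}
    if len(js) > 1:
        raise ValueError(f"inconsistent joint counts across sequences: {sorted(js)}")


def center_on_hips(seq: SkeletonSequence, joint_map: JointMap) -> SkeletonSequence:
    """Subtract the sequence-level mean of the three hip joints from every joint.

    One origin per sequence (mean over all frames), so within-sequence
    motion is preserved exactly; the operation is idempotent and removes
    any rigid translation of the whole recording.
    """
    hips = np.asarray(joint_map.hip_joints)
    if hips.max() >= seq.n_joints:
        raise IndexError("hip joints out of range")
    origin = seq.frames[:, hips, :].mean(axis=(0, 1))
    return SkeletonSequence(
        frames=seq.frames - origin,
        frame_rate=seq.frame_rate,
        label=seq.label,
        subject_id=seq.subject_id,
    )


def smooth_savgol(seq: SkeletonSequence, window: int = 5, polyorder: int = 2) -> SkeletonSequence:
    """Savitzky-Golay smoothing of each coordinate trajectory along time."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if seq.n_frames < window:
        raise ValueError(f"sequence length {seq.n_frames} < window {window}")
    flat = seq.frames.reshape(seq.n_frames, -1)
    smoothed = savgol_filter(flat, window_length=window, polyorder=polyorder, axis=0)
    return SkeletonSequence(
        frames=smoothed.reshape(seq.frames.shape),
        frame_rate=seq.frame_rate,
        label=seq.label,
        subject_id=seq.subject_id,
    )


def split_channels(seq: SkeletonSequence, joint_map: JointMap) -> ChannelSet:
    """Split a sequence into the five body-part channels.

    Each channel is the frame-wise concatenation of the (x, y, z) triples
    of the part's three joints, in joint-map order, giving a ``T x 9``
    series.  Discarded joints never appear.
    """
    channels: ChannelSet = {}
    for part in PARTS:
        joints = np.asarray(joint_map.part_to_joints[part])
        if joints.max() >= seq.n_joints:
            raise IndexError(f"part {part} joint index out of range")
        channels[part] = BodyPartChannel(
            part=part, series=seq.frames[:, joints, :].reshape(seq.n_frames, CHANNEL_DIM)
        )
    return channels


def pad_channel_sets(
    channel_sets: Sequence[ChannelSet],
    labels: Sequence[str],
    target_T: Optional[int] = None,
    split: Optional[Sequence[str]] = None,
) -> LabeledDataset:
    """Zero-pad every channel series at the end to a common length."""
    lengths = [next(iter(cs.values())).series.shape[0] for cs in channel_sets]
    if target_T is None:
        target_T = max(lengths)
    if target_T < max(lengths):
        raise ValueError(f"target_T={target_T} smaller than longest sequence {max(lengths)}")
    padded: List[ChannelSet] = []
    for cs in channel_sets:
        out: ChannelSet = {}
        for part, ch in cs.items():
            T = ch.series.shape[0]
            series = np.zeros((target_T, ch.series.shape[1]))
            series[:T] = ch.series
            out[part] = BodyPartChannel(part=part, series=series)
        padded.append(out)
    return LabeledDataset(
        channel_sets=padded,
        labels=list(labels),
        padded_length=target_T,
        split=list(split) if split is not None else None,
        lengths=lengths,
    )


# kept under the name used throughout the docs; alias for discoverability
pad_sequences = pad_channel_sets


def preprocess_sequences(
    seqs: Sequence[SkeletonSequence],
    joint_map: JointMap,
    window: int = 5,
    polyorder: int = 2,
    smooth: bool = True,
    target_T: Optional[int] = None,
    split: Optional[Sequence[str]] = None,
) -> LabeledDataset:
    """Full preprocessing chain: centre, smooth, split into channels, pad."""
    channel_sets: List[ChannelSet] = []
    labels: List[str] = []
    for seq in seqs:
        s = center_on_hips(seq, joint_map)
        if smooth and s.n_frames >= window:
            s = smooth_savgol(s, window=window, polyorder=polyorder)
        channel_sets.append(split_channels(s, joint_map))
        labels.append(seq.label if seq.label is not None else "?")
    return pad_channel_sets(channel_sets, labels, target_T=target_T, split=split)


def save_dataset_hdf5(dataset: LabeledDataset, path) -> None:
    """Write preprocessed per-channel series to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["padded_length"] = dataset.padded_length or -1
        for i, (cs, label) in enumerate(zip(dataset.channel_sets, dataset.labels)):
            grp = f.create_group(f"sample_{i:05d}")
            grp.attrs["label"] = label
            if dataset.split is not None:
                grp.attrs["split"] = dataset.split[i]
            for part, ch in cs.items():
                grp.create_dataset(part, data=ch.series)


def load_dataset_hdf5(path) -> LabeledDataset:
    channel_sets: List[ChannelSet] = []
    labels: List[str] = []
    split: List[str] = []
    has_split = False
    with h5py.File(path, "r") as f:
        padded = int(f.attrs.get("padded_length", -1))
        for name in sorted(f.keys()):
            grp = f[name]
            labels.append(str(grp.attrs["label"]))
            if "split" in grp.attrs:
                has_split = True
                split.append(str(grp.attrs["split"]))
            channel_sets.append(
                {part: BodyPartChannel(part=part, series=np.asarray(grp[part])) for part in PARTS}
            )
    return LabeledDataset(
        channel_sets=channel_sets,
        labels=labels,
        padded_length=padded if padded > 0 else None,
        split=split if has_split else None,
    )
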