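"""Seeded synthetic skeleton-action data and clustering fixtures.

Real skeleton action classes differ in which limbs oscillate, how fast
and how far; the generator emulates this with class-specific sinusoidal
limb trajectories around a fixed rest pose, additive Gaussian jitter
(sensor noise) and variable sequence lengths, producing either raw
``T x J x 3`` skeleton sequences (for I/O round-trips) or the five
9-dimensional body-part channels directly.  Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data_model import (
    CHANNEL_DIM,
    PARTS,
    BodyPartChannel,
    JointMap,
    LabeledDataset,
    SkeletonSequence,
    pad_channel_sets,
)

#: synthetic 16-joint skeleton: joint 0 is the hip centre (used only for
#: centring); three joints per part follow in a fixed order
SYNTH16_MAP = JointMap(
    part_to_joints={
        "CT": (1, 2, 3),
        "LA": (4, 5, 6),
        "RA": (7, 8, 9),
        "LL": (10, 11, 12),
        "RL": (13, 14, 15),
    },
    hip_joints=(0, 10, 13),
    discarded=(0,),
)

#: standing rest pose (metres-ish); rows follow the SYNTH16 joint order
_REST_POSE = np.array(
    [
        [0.0, 0.9, 0.0],  # hip centre
        [0.0, 1.2, 0.0],  # spine
        [0.0, 1.5, 0.0],  # neck
        [0.0, 1.65, 0.0],  # upper trunk
        [-0.25, 1.45, 0.0],  # L shoulder/elbow/wrist
        [-0.35, 1.2, 0.05],
        [-0.4, 0.95, 0.1],
        [0.25, 1.45, 0.0],  # R arm
        [0.35, 1.2, 0.05],
        [0.4, 0.95, 0.1],
        [-0.12, 0.9, 0.0],  # L hip/knee/ankle
        [-0.14, 0.5, 0.02],
        [-0.15, 0.1, 0.05],
        [0.12, 0.9, 0.0],  # R leg
        [0.14, 0.5, 0.02],
        [0.15, 0.1, 0.05],
    ]
)

#: proximal -> distal motion gain within a part's three joints
_JOINT_GAIN = np.array([0.5, 0.75, 1.0])


@dataclass(frozen=True)
class MotionClassSpec:
    """Sinusoidal signature of one action class.

    ``part_params`` maps each body part to (frequency in cycles/frame,
    amplitude, phase).  Distal joints move more than proximal ones, and
    the x/y/z coordinates of a joint are phase-staggered, so each part
    traces a 9-dimensional quasi-periodic trajectory.
    """

    name: str
    part_params: Dict[str, Tuple[float, float, float]]
    noise_sigma: float = 0.02
    length_range: Tuple[int, int] = (30, 40)

    def __post_init__(self) -> None:
        if set(self.part_params) != set(PARTS):
            raise ValueError(f"part_params must cover {PARTS}")
        if any(p[1] < 0 for p in self.part_params.values()):
            raise ValueError("amplitudes must be >= 0")
        if self.length_range[0] < 4:
            raise ValueError("T_min must be >= 4 (must exceed the largest kernel)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    classes: Tuple[MotionClassSpec, ...]
    samples_per_class: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need >= 2 classes for classification fixtures")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")


def default_class_specs(
    noise_sigma: float = 0.02, length_range: Tuple[int, int] = (30, 40)
) -> Tuple[MotionClassSpec, ...]:
    """Four action archetypes in disjoint frequency/limb-usage bands."""
    quiet = (0.01, 0.02, 0.0)
    return (
        MotionClassSpec(
            name="wave_arms",
            part_params={
                "LA": (0.10, 0.5, 0.0),
                "RA": (0.10, 0.5, np.pi),
                "CT": quiet,
                "LL": quiet,
                "RL": quiet,
            },
            noise_sigma=noise_sigma,
            length_range=length_range,
        ),
        MotionClassSpec(
            name="march",
            part_params={
                "LA": quiet,
                "RA": quiet,
                "CT": quiet,
                "LL": (0.06, 0.4, 0.0),
                "RL": (0.06, 0.4, np.pi),
            },
            noise_sigma=noise_sigma,
            length_range=length_range,
        ),
        MotionClassSpec(
            name="bend",
            part_params={
                "LA": (0.03, 0.15, 0.0),
                "RA": (0.03, 0.15, 0.0),
                "CT": (0.03, 0.45, 0.0),
                "LL": quiet,
                "RL": quiet,
            },
            noise_sigma=noise_sigma,
            length_range=length_range,
        ),
        MotionClassSpec(
            name="jump",
            part_params={
                "LA": (0.18, 0.3, 0.0),
                "RA": (0.18, 0.3, 0.0),
                "CT": (0.18, 0.25, 0.0),
                "LL": (0.18, 0.3, np.pi / 2),
                "RL": (0.18, 0.3, np.pi / 2),
            },
            noise_sigma=noise_sigma,
            length_range=length_range,
        ),
    )


def _part_trajectory(
    spec: MotionClassSpec, part: str, T: int, rng: np.random.Generator
) -> np.ndarray:
    """T x 9 raw coordinate series of one part (3 joints x xyz)."""
    freq, amp, phase = spec.part_params[part]
    joints = SYNTH16_MAP.part_to_joints[part]
    rest = _REST_POSE[list(joints)]  # 3 x 3
    t = np.arange(1, T + 1)[:, None, None]
    # stagger the three coordinates of a joint so the motion is genuinely 3-D
    coord_phase = np.array([0.0, np.pi / 3, 2 * np.pi / 3])[None, None, :]
    gain = _JOINT_GAIN[None, :, None]
    wave = amp * gain * np.sin(2 * np.pi * freq * t + phase + coord_phase)
    series = rest[None, :, :] + wave
    if spec.noise_sigma > 0:
        series = series + rng.normal(0.0, spec.noise_sigma, size=series.shape)
    return series.reshape(T, CHANNEL_DIM)


def _check_distinct(classes: Sequence[MotionClassSpec]) -> None:
    seen = set()
    for spec in classes:
        key = tuple(sorted((p, tuple(v)) for p, v in spec.part_params.items()))
        if key in seen:
            warnings.warn(
                "degenerate generator config: identical class specs", stacklevel=3
            )
        seen.add(key)


def generate_action_dataset(cfg: GeneratorConfig) -> LabeledDataset:
    """Labeled five-channel dataset of class-specific periodic motions.

    Sample lengths are drawn uniformly from each class's length range
    and all channels are zero-padded to the longest generated length.
    """
    _check_distinct(cfg.classes)
    rng = np.random.default_rng(cfg.seed)
    channel_sets = []
    labels: List[str] = []
    for spec in cfg.classes:
        for _ in range(cfg.samples_per_class):
            T = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            cs = {
                part: BodyPartChannel(part=part, series=_part_trajectory(spec, part, T, rng))
                for part in PARTS
            }
            channel_sets.append(cs)
            labels.append(spec.name)
    return pad_channel_sets(channel_sets, labels)


def generate_skeleton_sequences(cfg: GeneratorConfig) -> List[SkeletonSequence]:
    """Same motions as raw 16-joint skeleton sequences (for I/O round-trips)."""
    _check_distinct(cfg.classes)
    rng = np.random.default_rng(cfg.seed)
    seqs: List[SkeletonSequence] = []
    for spec in cfg.classes:
        for _ in range(cfg.samples_per_class):
            T = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            frames = np.tile(_REST_POSE[None, :, :], (T, 1, 1))
            for part in PARTS:
                joints = list(SYNTH16_MAP.part_to_joints[part])
                frames[:, joints, :] = _part_trajectory(spec, part, T, rng).reshape(T, 3, 3)
            seqs.append(SkeletonSequence(frames=frames, label=spec.name))
    return seqs


def assign_split(
    labels: Sequence[str],
    val_fraction: float = 0.25,
    test_fraction: float = 0.0,
    seed: int = 0,
) -> List[str]:
    """Stratified train/val(/test) membership per sample."""
    labels = list(labels)
    rng = np.random.default_rng(seed)
    split = ["train"] * len(labels)
    for cls in sorted(set(labels)):
        idx = np.array([i for i, l in enumerate(labels) if l == cls])
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        n_test = int(round(test_fraction * len(idx)))
        for i in idx[:n_val]:
            split[int(i)] = "val"
        for i in idx[n_val : n_val + n_test]:
            split[int(i)] = "test"
    return split


def generate_gaussian_mixture(
    centers: Sequence[Sequence[float]],
    sigma: float,
    n_per_center: int,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian blobs; the SORN parameter-recovery fixture.

    Returns (points, center_index) with points shuffled.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    centers_arr = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers_arr.shape[0] < 1:
        raise ValueError("need at least one center")
    rng = np.random.default_rng(seed)
    pts = []
    labels = []
    for i, c in enumerate(centers_arr):
        pts.append(c + rng.normal(0.0, sigma, size=(n_per_center, centers_arr.shape[1])))
        labels.append(np.full(n_per_center, i))
    points = np.vstack(pts)
    labels_arr = np.concatenate(labels)
    perm = rng.permutation(points.shape[0])
    return points[perm], labels_arr[perm]
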