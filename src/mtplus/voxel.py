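"""Voxel-level stage: binarization, group maps, and the MPM dominance rule.

Per-subject streamline visitation volumes are binarized without any
threshold (a voxel counts as connected iff at least one streamline visited
it), combined into group probabilistic maps (fraction of subjects connected
per voxel) and group-average strength volumes, and white-matter voxels are
classified with a modified maximum-probability-map rule: a voxel belongs
dominantly to seed X iff X has the strictly largest averaged strength and,
against every other seed Y, ``|S_X - S_Y| > (S_X + S_Y) / 2`` -- which for
nonnegative strengths with ``S_X > S_Y`` is exactly ``S_X > 3 S_Y``.
Voxels with all-zero strengths are UNCLASSIFIED (not connected at all);
every other connected voxel is OVERLAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

SEEDS = ("MST", "MT", "FST")

# integer label codes for the MPM volume
BACKGROUND = -1  # outside the analysis mask
UNCLASSIFIED = 0  # inside the mask, zero strength for every seed
OVERLAP = 4
SEED_CODES = {"MST": 1, "MT": 2, "FST": 3}
CODE_NAMES = {
    BACKGROUND: "BACKGROUND",
    UNCLASSIFIED: "UNCLASSIFIED",
    1: "MST",
    2: "MT",
    3: "FST",
    OVERLAP: "OVERLAP",
}


@dataclass
class ProfileVolume:
    """Per-subject, per-seed 3D grid of streamline visitation counts."""

    counts: np.ndarray
    seed_id: str
    subject_id: str
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3D volume")
        if np.any(self.counts < 0):
            raise ValueError("streamline counts must be nonnegative")


@dataclass
class BinaryProfile:
    """Thresholdless presence/absence indicator of streamlines per voxel."""

    mask: np.ndarray
    seed_id: str
    subject_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class GroupProbMap:
    """Per-voxel fraction of subjects whose binarized profile is 1."""

    fraction: np.ndarray
    seed_id: str
    n_subjects: int


@dataclass
class MPMLabelVolume:
    """Integer-coded dominance labels plus the averaged strengths behind them."""

    labels: np.ndarray
    strengths: dict[str, np.ndarray] = field(default_factory=dict)
    seed_order: tuple[str, ...] = SEEDS

    def label_names(self) -> dict[int, str]:
        return dict(CODE_NAMES)


def binarize_profile(profile: ProfileVolume) -> BinaryProfile:
    """Voxel = 1 iff its streamline count is positive; no threshold exists."""
    return BinaryProfile(
        mask=profile.counts > 0,
        seed_id=profile.seed_id,
        subject_id=profile.subject_id,
    )


def _check_stackable(items: Sequence, what: str) -> None:
    if len(items) == 0:
        raise ValueError(f"need at least one {what}")
    seed = items[0].seed_id
    shape = (items[0].mask if hasattr(items[0], "mask") else items[0].counts).shape
    for it in items:
        arr = it.mask if hasattr(it, "mask") else it.counts
        if it.seed_id != seed:
            raise ValueError(f"mixed seeds: {it.seed_id} vs {seed}")
        if arr.shape != shape:
            raise ValueError(f"mismatched grids: {arr.shape} vs {shape}")


def group_probability_map(profiles: Sequence[BinaryProfile]) -> GroupProbMap:
    """Fraction of subjects with a streamline at each voxel, one seed."""
    _check_stackable(profiles, "binary profile")
    stack = np.stack([p.mask for p in profiles]).astype(float)
    return GroupProbMap(
        fraction=stack.mean(axis=0),
        seed_id=profiles[0].seed_id,
        n_subjects=len(profiles),
    )


def group_average_profile(profiles: Sequence[ProfileVolume]) -> np.ndarray:
    """Arithmetic mean of the visitation counts across subjects, one seed."""
    _check_stackable(profiles, "profile")
    return np.stack([p.counts for p in profiles]).astype(float).mean(axis=0)


def classify_mpm(
    averaged: Mapping[str, np.ndarray],
    wm_mask: np.ndarray,
    seed_order: Sequence[str] = SEEDS,
) -> MPMLabelVolume:
    """Dominance classification of mask voxels from averaged seed strengths.

    Parameters
    ----------
    averaged:
        Mapping from seed id to its group-averaged strength volume; all
        volumes co-registered (identical shape) and nonnegative.
    wm_mask:
        Boolean analysis mask (white matter in the tract analysis).

    Within the mask a voxel is labeled with seed X iff X's strength is the
    unique maximum and exceeds three times every other seed's strength
    (equivalent to the half-sum margin rule); all-zero voxels are
    UNCLASSIFIED; every other voxel is OVERLAP.  Outside the mask the label
    is BACKGROUND.
    """
    seed_order = tuple(seed_order)
    if set(seed_order) - set(averaged):
        raise ValueError("averaged strengths missing for some seeds")
    vols = [np.asarray(averaged[s], dtype=float) for s in seed_order]
    shape = vols[0].shape
    for v in vols:
        if v.shape != shape:
            raise ValueError("averaged volumes are not co-registered")
        if np.any(v < 0):
            raise ValueError("averaged strengths must be nonnegative")
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if wm_mask.shape != shape:
        raise ValueError("mask shape does not match strength volumes")

    stack = np.stack(vols)  # (n_seeds, *shape)
    labels = np.full(shape, BACKGROUND, dtype=np.int8)
    labels[wm_mask] = OVERLAP
    labels[wm_mask & np.all(stack == 0, axis=0)] = UNCLASSIFIED

    for k, seed in enumerate(seed_order):
        s_x = stack[k]
        others = [stack[j] for j in range(len(seed_order)) if j != k]
        dominant = wm_mask & (s_x > 0)
        for s_y in others:
            dominant &= s_x > 3.0 * s_y
        labels[dominant] = SEED_CODES[seed]

    return MPMLabelVolume(
        labels=labels,
        strengths={s: v for s, v in zip(seed_order, vols)},
        seed_order=seed_order,
    )


def overlap_fraction(mpm: MPMLabelVolume) -> float:
    """Percentage of classified voxels labeled OVERLAP.

    The denominator counts voxels labeled with a seed or OVERLAP;
    UNCLASSIFIED (zero-strength) and background voxels are excluded.
    Raises if no voxel is classified.
    """
    labels = mpm.labels
    classified = np.isin(labels, list(SEED_CODES.values()) + [OVERLAP])
    n_classified = int(classified.sum())
    if n_classified == 0:
        raise ValueError("overlap fraction undefined: no classified voxels")
    n_overlap = int((labels == OVERLAP).sum())
    return 100.0 * n_overlap / n_classified
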