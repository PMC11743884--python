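"""ROI-level stage: connectome normalization, seed fingerprints, similarity sets.

Streamline-count matrices are normalized by node size (the inverse-mean-
volume convention ``w_ab = c_ab * 2 / (V_a + V_b)``), averaged into a group
connectome, and each MT+ seed's connectivity vector over a union of
top-fraction target regions becomes its fingerprint.  Fingerprints are
compared with average-rank Spearman correlations, within and between seeds
across subjects, and Fisher z-transformed for downstream group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SEEDS = ("MST", "MT", "FST")


@dataclass
class ConnectomeMatrix:
    """Symmetric nonnegative ROI x ROI strength matrix with labels and volumes.

    ``weights[i, j]`` is the (normalized) streamline strength between regions
    ``labels[i]`` and ``labels[j]``; the diagonal is zero.  ``node_volumes``
    holds region sizes (voxel counts or mm^3) when known.
    """

    weights: np.ndarray
    labels: tuple[str, ...]
    node_volumes: np.ndarray | None = None
    subject_id: str = "group"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("connectome matrix must be symmetric")
        if np.any(self.weights < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("connectome diagonal must be zero")
        if self.node_volumes is not None:
            self.node_volumes = np.asarray(self.node_volumes, dtype=float)
            if self.node_volumes.shape != (n,):
                raise ValueError("node_volumes length must match labels")
            if np.any(self.node_volumes <= 0):
                raise ValueError("node volumes must be positive")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label: {label}") from None

    def row(self, label: str) -> pd.Series:
        """Connectivity vector of one region over all regions."""
        return pd.Series(self.weights[self.index(label)], index=self.labels)


@dataclass
class SeedVector:
    """Connectivity fingerprint of one seed over a fixed target list."""

    seed_id: str
    target_labels: tuple[str, ...]
    strengths: np.ndarray
    subject_id: str = "group"

    def __post_init__(self) -> None:
        self.target_labels = tuple(self.target_labels)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.strengths.shape != (len(self.target_labels),):
            raise ValueError("strengths length must match target_labels")
        if set(SEEDS) & set(self.target_labels):
            raise ValueError("targets must exclude the MT+ seeds themselves")


@dataclass
class SimilaritySets:
    """Within-seed and between-seed Spearman similarity sets across subjects.

    ``set_aa`` holds the n(n-1)/2 within-seed correlations of seed A across
    subject pairs; ``set_ab`` the direction-averaged between-seed
    correlations of seeds A and B; ``fisher_z_*`` the variance-stabilized
    copies used by group statistics.
    """

    seed_a: str
    seed_b: str
    n: int
    set_aa: np.ndarray
    set_bb: np.ndarray
    set_ab: np.ndarray
    fisher_z_aa: np.ndarray = field(init=False)
    fisher_z_bb: np.ndarray = field(init=False)
    fisher_z_ab: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        expected = self.n * (self.n - 1) // 2
        for name in ("set_aa", "set_bb", "set_ab"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (expected,):
                raise ValueError(
                    f"{name} must have n(n-1)/2 = {expected} elements"
                )
            setattr(self, name, arr)
        self.fisher_z_aa = fisher_z(self.set_aa)
        self.fisher_z_bb = fisher_z(self.set_bb)
        self.fisher_z_ab = fisher_z(self.set_ab)


def normalize_by_node_size(
    raw_counts: np.ndarray,
    node_volumes: np.ndarray,
    labels: Sequence[str],
    subject_id: str = "group",
) -> ConnectomeMatrix:
    """Scale each edge count by the inverse mean volume of its two nodes.

    ``w_ab = c_ab * 2 / (V_a + V_b)``, so connections between large regions
    are not inflated merely because more streamlines can terminate there.
    """
    counts = np.asarray(raw_counts, dtype=float)
    vols = np.asarray(node_volumes, dtype=float)
    if np.any(vols <= 0):
        raise ValueError("node volumes must be strictly positive")
    scale = 2.0 / (vols[:, None] + vols[None, :])
    return ConnectomeMatrix(
        weights=counts * scale,
        labels=labels,
        node_volumes=vols,
        subject_id=subject_id,
    )


def group_average_connectome(stack: Sequence[ConnectomeMatrix]) -> ConnectomeMatrix:
    """Entrywise mean of per-subject connectomes sharing one label order."""
    if len(stack) == 0:
        raise ValueError("need at least one connectome")
    labels = stack[0].labels
    for c in stack:
        if c.labels != labels:
            raise ValueError("connectome label orders differ; cannot average")
    mean = np.mean([c.weights for c in stack], axis=0)
    vols = stack[0].node_volumes
    return ConnectomeMatrix(mean, labels, node_volumes=vols, subject_id="group")


def top_fraction_union(
    group: ConnectomeMatrix,
    seeds: Sequence[str] = SEEDS,
    fraction: float = 0.5,
) -> list[str]:
    """Union of each seed's top-fraction most-connected non-seed regions.

    For each seed the non-seed regions are ranked by group connectivity
    strength (descending, ties broken by label) and the top
    ``ceil(fraction * m)`` retained; the three lists are combined.  The
    union is returned in label-sorted order for reproducibility.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    seeds = list(seeds)
    for s in seeds:
        group.index(s)  # raises on unknown seed
    candidates = [lab for lab in group.labels if lab not in seeds]
    m = len(candidates)
    k = ceil(fraction * m)
    union: set[str] = set()
    for s in seeds:
        row = group.row(s)
        ranked = sorted(candidates, key=lambda lab: (-row[lab], lab))
        union.update(ranked[:k])
    return sorted(union)


def seed_vector(
    conn: ConnectomeMatrix, seed: str, targets: Sequence[str]
) -> SeedVector:
    """Extract one seed's fingerprint over an explicit target list."""
    row = conn.row(seed)
    return SeedVector(
        seed_id=seed,
        target_labels=targets,
        strengths=row[list(targets)].to_numpy(),
        subject_id=conn.subject_id,
    )


def seed_pattern_correlation(
    v_a: SeedVector, v_b: SeedVector, n_tests: int = 6
) -> tuple[float, float]:
    """Spearman correlation of two seed fingerprints, Bonferroni-adjusted.

    Returns ``(rho, p_adjusted)`` with ``p_adjusted = min(1, p * n_tests)``.
    The two vectors must cover the same targets in the same order.
    """
    if v_a.target_labels != v_b.target_labels:
        raise ValueError("seed vectors cover different target lists")
    if len(v_a.target_labels) < 3:
        raise ValueError("need at least 3 targets for a rank correlation")
    rho, p = stats.spearmanr(v_a.strengths, v_b.strengths)
    return float(rho), float(min(1.0, p * n_tests))


def similarity_sets(
    vectors_a: Sequence[SeedVector], vectors_b: Sequence[SeedVector]
) -> SimilaritySets:
    """Within- and between-seed fingerprint similarity across subject pairs.

    ``set_aa = {rho(v_i^A, v_j^A) : i < j}`` measures how reproducible seed
    A's fingerprint is across subjects; ``set_ab`` averages the two
    cross-subject, cross-seed correlations ``(rho(v_i^A, v_j^B) +
    rho(v_i^B, v_j^A)) / 2`` so that it is symmetric in A and B.
    """
    n = len(vectors_a)
    if len(vectors_b) != n:
        raise ValueError("seed A and seed B must have the same subjects")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    targets = vectors_a[0].target_labels
    for v in (*vectors_a, *vectors_b):
        if v.target_labels != targets:
            raise ValueError("all vectors must share one aligned target list")

    mat_a = np.stack([v.strengths for v in vectors_a])
    mat_b = np.stack([v.strengths for v in vectors_b])
    # rank once per subject-vector, then Pearson on ranks == Spearman
    ra = np.apply_along_axis(stats.rankdata, 1, mat_a)
    rb = np.apply_along_axis(stats.rankdata, 1, mat_b)

    def _corr(x: np.ndarray, y: np.ndarray) -> float:
        return float(np.corrcoef(x, y)[0, 1])

    aa, bb, ab = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            aa.append(_corr(ra[i], ra[j]))
            bb.append(_corr(rb[i], rb[j]))
            ab.append((_corr(ra[i], rb[j]) + _corr(rb[i], ra[j])) / 2.0)

    return SimilaritySets(
        seed_a=vectors_a[0].seed_id,
        seed_b=vectors_b[0].seed_id,
        n=n,
        set_aa=np.array(aa),
        set_bb=np.array(bb),
        set_ab=np.array(ab),
    )


def fisher_z(rho: np.ndarray | float, clip: float = 1e-7) -> np.ndarray | float:
    """Fisher z (arctanh) transform, clipping |rho| to 1 - ``clip``.

    Clipping keeps the transform finite when degenerate data yield a
    correlation of exactly +/-1.
    """
    arr = np.asarray(rho, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(arr, -1 + clip, 1 - clip))
    return float(z) if np.isscalar(rho) or arr.ndim == 0 else z
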