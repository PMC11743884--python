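"""Synthetic multi-subject connectomes and voxel profiles with known ground truth.

The generator emulates the structure of a two-species diffusion study
without simulating diffusion or tractography:

* **ROI level** -- each seed (MST, MT, FST) has a latent log-normal
  connectivity vector over the target regions.  The three vectors are drawn
  through a Gaussian copula whose correlation matrix is calibrated so that
  their *rank* correlations match a requested 3x3 target (human-like
  fingerprints are nearly interchangeable, target ~0.9; macaque-like ones
  diverge, target ~0.2).  Per-subject matrices multiply the latent values
  by log-normal noise, and raw "streamline counts" are back-scaled by node
  volume so that the inverse-mean-volume normalization recovers the
  strengths exactly.
* **voxel level** -- a shared smooth positive base field plays the role of
  anatomy; each seed's expected count is modulated along the dorso-ventral
  grid axis (axis 2) by a logistic bump whose center is dorsal for MST,
  middle for MT and ventral for FST.  ``gradient_strength = 0`` switches
  the modulation off, giving identical expected profiles for all seeds
  (human-like); large values segregate the seeds (macaque-like).  Counts
  are Poisson around the subject-scaled rate.
* **tracer table** -- two directed entries per undirected connection of a
  chosen seed, each the true strength times independent log-normal noise.

All randomness derives from ``rng_seed``; regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mtplus.roi import ConnectomeMatrix
from mtplus.voxel import ProfileVolume

SEEDS = ("MST", "MT", "FST")

# dorso-ventral bump centers on the unit axis (1 = dorsal-most slice)
_BUMP_CENTERS = {"MST": 5.0 / 6.0, "MT": 0.5, "FST": 1.0 / 6.0}
_BUMP_HALFWIDTH = 1.0 / 6.0
_LOGNORMAL_SIGMA = 1.0  # marginal log-sd of latent strengths


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped simulation parameters.

    ``target_pattern_correlation`` is the desired Spearman correlation
    matrix of the three latent seed fingerprints; ``subject_noise_sd`` the
    log-sd of the multiplicative subject noise; ``gradient_strength`` the
    steepness of the dorso-ventral dominance gradient in the voxel arm
    (0 = none).
    """

    n_subjects: int = 30
    n_regions: int = 80
    target_pattern_correlation: tuple = ((1.0, 0.9, 0.9), (0.9, 1.0, 0.9), (0.9, 0.9, 1.0))
    subject_noise_sd: float = 0.3
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    gradient_strength: float = 0.0
    mean_count: float = 20.0
    rng_seed: int = 0
    n_seeds: int = field(default=3, repr=False)

    def __post_init__(self) -> None:
        if self.n_seeds != 3:
            raise ValueError("the MT+ analysis is defined for exactly 3 seeds")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_regions < 4:
            raise ValueError("need at least 4 target regions")
        if len(self.grid_shape) != 3 or any(d < 4 for d in self.grid_shape):
            raise ValueError("grid_shape must be 3 dims, each >= 4")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be nonnegative")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be nonnegative")
        if self.mean_count <= 0:
            raise ValueError("mean_count must be positive")
        t = self.target_matrix()
        if t.shape != (3, 3):
            raise ValueError("target_pattern_correlation must be 3x3")
        if not np.allclose(t, t.T) or not np.allclose(np.diag(t), 1.0):
            raise ValueError(
                "target_pattern_correlation must be symmetric with unit diagonal"
            )
        if np.any(np.abs(t) > 1):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(t).min() < -1e-10:
            raise ValueError(
                "target_pattern_correlation is not positive semidefinite"
            )

    def target_matrix(self) -> np.ndarray:
        return np.asarray(self.target_pattern_correlation, dtype=float)

    @classmethod
    def human_like(cls, **overrides) -> "SyntheticConfig":
        """Interchangeable seed fingerprints, no dorso-ventral gradient."""
        defaults = dict(
            target_pattern_correlation=_offdiag(0.9),
            gradient_strength=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def macaque_like(cls, **overrides) -> "SyntheticConfig":
        """Divergent seed fingerprints and a strong dorso-ventral gradient."""
        defaults = dict(
            target_pattern_correlation=_offdiag(0.2),
            gradient_strength=30.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def _rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator component."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.rng_seed) % (2**31), stream])
        )


def _offdiag(r: float) -> tuple:
    return tuple(
        tuple(1.0 if i == j else float(r) for j in range(3)) for i in range(3)
    )


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Gaussian-copula calibration: Pearson latent correlation that yields
    a requested Spearman correlation, ``r = 2 sin(pi rho_s / 6)``."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def region_labels(n_regions: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n_regions)]


def _latent_seed_vectors(config: SyntheticConfig, rng: np.random.Generator):
    """Draw latent seed-by-target strengths through the Gaussian copula."""
    pearson = spearman_to_pearson(config.target_matrix())
    np.fill_diagonal(pearson, 1.0)
    # nudge onto the PSD cone if the sin transform pushed it marginally off
    eigvals, eigvecs = np.linalg.eigh(pearson)
    if eigvals.min() < 0:
        pearson = (eigvecs * np.maximum(eigvals, 0)) @ eigvecs.T
        d = np.sqrt(np.diag(pearson))
        pearson = pearson / np.outer(d, d)
    chol = np.linalg.cholesky(pearson + 1e-12 * np.eye(3))
    z = rng.standard_normal((config.n_regions, 3)) @ chol.T  # copula draws
    strengths = np.exp(_LOGNORMAL_SIGMA * z)  # log-normal marginals, median 1
    return strengths.T  # (3 seeds, n_regions)


def _lognormal_noise(
    rng: np.random.Generator, sd: float, shape: tuple
) -> np.ndarray:
    if sd == 0:
        return np.ones(shape)
    return np.exp(sd * rng.standard_normal(shape))


def generate_roi_connectomes(
    config: SyntheticConfig,
) -> tuple[list[ConnectomeMatrix], pd.DataFrame]:
    """Per-subject raw-count connectomes plus the latent seed fingerprints.

    Returns ``(subjects, latent)`` where each subject matrix holds raw
    streamline counts (normalize with
    :func:`mtplus.roi.normalize_by_node_size` to recover strengths) and
    ``latent`` is the 3 x n_regions ground-truth strength table (rows MST,
    MT, FST).  With ``subject_noise_sd = 0`` every subject's normalized
    seed vectors equal the latent vectors exactly.
    """
    rng = config._rng(1)
    n_t = config.n_regions
    labels = list(SEEDS) + region_labels(n_t)
    n = len(labels)

    latent_seed = _latent_seed_vectors(config, rng)  # (3, n_t)
    # background structure: target-target and seed-seed strengths, iid log-normal
    bg = np.exp(_LOGNORMAL_SIGMA * rng.standard_normal((n, n)))
    bg = np.triu(bg, k=1)
    truth = bg + bg.T
    truth[:3, 3:] = latent_seed
    truth[3:, :3] = latent_seed.T
    np.fill_diagonal(truth, 0.0)

    # node volumes shared across subjects; raw counts carry the volume factor
    # back in so that inverse-mean-volume normalization recovers strengths
    vols = np.exp(0.3 * rng.standard_normal(n))
    vol_factor = (vols[:, None] + vols[None, :]) / 2.0

    subjects = []
    for i in range(config.n_subjects):
        noise = _lognormal_noise(rng, config.subject_noise_sd, (n, n))
        noise = np.triu(noise, k=1)
        noise = noise + noise.T
        noise[noise == 0] = 1.0
        counts = truth * noise * vol_factor
        np.fill_diagonal(counts, 0.0)
        subjects.append(
            ConnectomeMatrix(
                weights=counts,
                labels=labels,
                node_volumes=vols,
                subject_id=f"sub-{i + 1:03d}",
            )
        )

    latent = pd.DataFrame(latent_seed, index=list(SEEDS), columns=region_labels(n_t))
    return subjects, latent


def _seed_axis_weight(
    seed: str, z_positions: np.ndarray, gradient_strength: float
) -> np.ndarray:
    """Plateau bump along the dorso-ventral axis, flat when strength is 0.

    Product of two logistics centered ``_BUMP_HALFWIDTH`` either side of the
    seed's preferred position; at strength 0 both factors are 1/2, so every
    seed gets the identical constant weight 1/4.
    """
    c = _BUMP_CENTERS[seed]
    g = gradient_strength
    lo = 1.0 / (1.0 + np.exp(-g * (z_positions - (c - _BUMP_HALFWIDTH))))
    hi = 1.0 / (1.0 + np.exp(g * (z_positions - (c + _BUMP_HALFWIDTH))))
    return lo * hi


def generate_voxel_profiles(
    config: SyntheticConfig,
) -> tuple[dict[str, dict[str, ProfileVolume]], np.ndarray, np.ndarray]:
    """Per-subject, per-seed visitation-count volumes plus tissue masks.

    Returns ``(profiles, gm_mask, wm_mask)`` with
    ``profiles[subject_id][seed_id]`` a :class:`ProfileVolume`.  The grid is
    split into a gray-matter compartment (lower half of axis 0) and a
    white-matter compartment (upper half); axis 2 is dorso-ventral with
    index 0 ventral.
    """
    rng = config._rng(2)
    shape = tuple(config.grid_shape)
    nx, ny, nz = shape

    gm_mask = np.zeros(shape, dtype=bool)
    wm_mask = np.zeros(shape, dtype=bool)
    gm_mask[: nx // 2] = True
    wm_mask[nx // 2 :] = True

    # shared smooth positive "anatomy" field, mean 1
    from scipy.ndimage import gaussian_filter

    base = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    base = 1.0 + base / (3.0 * max(base.std(), 1e-12))
    base = np.clip(base, 0.05, None)
    base /= base.mean()

    z_positions = np.linspace(0.0, 1.0, nz)
    seed_weight = {
        s: _seed_axis_weight(s, z_positions, config.gradient_strength)
        for s in SEEDS
    }

    profiles: dict[str, dict[str, ProfileVolume]] = {}
    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:03d}"
        profiles[sid] = {}
        for seed in SEEDS:
            rate = (
                config.mean_count
                * base
                * (seed_weight[seed][None, None, :] / 0.25)
            )
            subject_factor = float(
                _lognormal_noise(rng, config.subject_noise_sd, ())
            )
            counts = rng.poisson(rate * subject_factor)
            profiles[sid][seed] = ProfileVolume(
                counts=counts, seed_id=seed, subject_id=sid
            )
    return profiles, gm_mask, wm_mask


def generate_tracer_table(
    config: SyntheticConfig,
    truth: ConnectomeMatrix,
    seed_region: str = "MT",
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Directed tracer-style strengths for one seed's connections.

    For every region with a nonzero true connection to ``seed_region`` two
    directed rows are emitted (seed->region and region->seed), each the true
    strength times independent log-normal noise of log-sd ``noise_sd``
    (defaults to ``config.subject_noise_sd``).  Zero noise reproduces the
    truth in both directions.
    """
    if noise_sd is None:
        noise_sd = config.subject_noise_sd
    rng = config._rng(3)
    row = truth.row(seed_region)
    rows = []
    for region, strength in row.items():
        if region == seed_region or strength == 0:
            continue
        out_noise, in_noise = _lognormal_noise(rng, noise_sd, (2,))
        rows.append(
            {"source": seed_region, "target": region,
             "strength": strength * out_noise}
        )
        rows.append(
            {"source": region, "target": seed_region,
             "strength": strength * in_noise}
        )
    return pd.DataFrame(rows, columns=["source", "target", "strength"])
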