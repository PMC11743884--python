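"""Common-space stage: homolog projection, cross-species fingerprints, tracer concordance.

Group connectomes of each species are projected onto a shared set of 27
homologous cortical regions; the 3 seeds x 27 homologs strength table is
jointly ranked and each seed's fingerprint compared across species by
Spearman correlation (Bonferroni-corrected over the three seeds).  A
directed tracer-strength table (e.g., retrograde-labeling fractions) can be
symmetrized, aggregated onto the diffusion atlas, and correlated with the
corresponding diffusion-derived seed vector as a concordance check.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mtplus.roi import ConnectomeMatrix, SeedVector

SEEDS = ("MST", "MT", "FST")
LOBES = ("frontal", "parietal", "temporal", "occipital")


@dataclass
class HomologyTable:
    """Mapping from species atlas labels to shared homolog names.

    One row per (species, atlas_label); several atlas labels may map to the
    same homolog (aggregation is by summation, since streamline strengths
    are extensive).  Every homolog must be present for every species in the
    table, and each homolog carries a lobe tag for plotting.
    """

    table: pd.DataFrame

    REQUIRED = ("species", "atlas_label", "homolog", "lobe")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"homology table missing columns: {sorted(missing)}")
        bad_lobes = set(self.table["lobe"]) - set(LOBES)
        if bad_lobes:
            raise ValueError(f"unknown lobes: {sorted(bad_lobes)}")
        per_species = self.table.groupby("species")["homolog"].agg(set)
        universe = set(self.table["homolog"])
        for species, homs in per_species.items():
            if homs != universe:
                raise ValueError(
                    f"species {species!r} is missing homologs: "
                    f"{sorted(universe - homs)}"
                )

    @property
    def homologs(self) -> list[str]:
        """Homolog names in first-appearance order."""
        return list(dict.fromkeys(self.table["homolog"]))

    def lobe_of(self, homolog: str) -> str:
        rows = self.table.loc[self.table["homolog"] == homolog, "lobe"]
        if rows.empty:
            raise KeyError(f"unknown homolog: {homolog}")
        return rows.iloc[0]

    def mapping_for(self, species: str) -> dict[str, list[str]]:
        """homolog -> atlas labels for one species."""
        sub = self.table[self.table["species"] == species]
        if sub.empty:
            raise KeyError(f"no homology rows for species {species!r}")
        out: dict[str, list[str]] = {}
        for hom, grp in sub.groupby("homolog", sort=False):
            out[hom] = list(grp["atlas_label"])
        return {h: out[h] for h in self.homologs}

    @classmethod
    def from_csv(cls, path: str | Path) -> "HomologyTable":
        return cls(pd.read_csv(path, dtype=str))

    @classmethod
    def default(cls) -> "HomologyTable":
        """The packaged 27-homolog table (editable CSV shipped with the package)."""
        with resources.files("mtplus").joinpath("data/homology27.csv").open() as fh:
            return cls(pd.read_csv(fh, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class CommonSpaceProfile:
    """Seed x homolog strengths of one species, with joint ranks.

    Ranks are computed over all seeds-times-homologs values together
    (average ranks on ties), which is how the fingerprints are visualized;
    Spearman comparisons are identical on strengths or joint ranks.
    """

    species: str
    strengths: pd.DataFrame  # index: seeds, columns: homologs
    joint_ranks: pd.DataFrame

    def __post_init__(self) -> None:
        if self.joint_ranks.shape != self.strengths.shape:
            raise ValueError("joint_ranks shape must match strengths")

    def tidy(self, homology: HomologyTable | None = None) -> pd.DataFrame:
        """Long format (seed, homolog, lobe, strength, joint_rank) for plotting."""
        rows = []
        for seed in self.strengths.index:
            for hom in self.strengths.columns:
                rows.append(
                    {
                        "species": self.species,
                        "seed": seed,
                        "homolog": hom,
                        "lobe": homology.lobe_of(hom) if homology else "",
                        "strength": self.strengths.loc[seed, hom],
                        "joint_rank": self.joint_ranks.loc[seed, hom],
                    }
                )
        return pd.DataFrame(rows)


def project_to_common_space(
    group: ConnectomeMatrix,
    homology: HomologyTable,
    species: str,
    seeds: Sequence[str] = SEEDS,
) -> CommonSpaceProfile:
    """Aggregate a group connectome's seed rows onto the homolog set.

    ``strength(seed, homolog)`` is the sum of the seed's weights to every
    atlas label mapped to that homolog.  All mapped labels must exist in the
    connectome.
    """
    mapping = homology.mapping_for(species)
    known = set(group.labels)
    missing = sorted(
        {lab for labs in mapping.values() for lab in labs} - known
    )
    if missing:
        raise ValueError(
            f"atlas labels in the homology table are absent from the "
            f"connectome: {missing}"
        )
    homologs = list(mapping)
    data = np.zeros((len(seeds), len(homologs)))
    for i, seed in enumerate(seeds):
        row = group.row(seed)
        for j, hom in enumerate(homologs):
            data[i, j] = sum(row[lab] for lab in mapping[hom])
    strengths = pd.DataFrame(data, index=list(seeds), columns=homologs)
    ranks = stats.rankdata(data, axis=None).reshape(data.shape)
    joint_ranks = pd.DataFrame(ranks, index=list(seeds), columns=homologs)
    return CommonSpaceProfile(species, strengths, joint_ranks)


def cross_species_seed_correlation(
    profile_a: CommonSpaceProfile,
    profile_b: CommonSpaceProfile,
    seed: str,
    n_tests: int = 3,
) -> tuple[float, float]:
    """Spearman correlation of one seed's homolog fingerprint across species.

    Returns ``(rho, p_adjusted)`` with Bonferroni adjustment over
    ``n_tests`` (one test per seed by default).
    """
    cols_a = list(profile_a.strengths.columns)
    cols_b = list(profile_b.strengths.columns)
    if cols_a != cols_b:
        raise ValueError("homolog order differs between the two profiles")
    x = profile_a.strengths.loc[seed].to_numpy()
    y = profile_b.strengths.loc[seed].to_numpy()
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(min(1.0, p * n_tests))


def symmetrize_tracer(tracer: pd.DataFrame) -> pd.DataFrame:
    """Collapse a directed tracer table to undirected strengths.

    Input columns ``source, target, strength``; at most one entry per
    ordered pair.  For each unordered pair the undirected strength is the
    mean of the two directed entries when both exist, else the single
    existing entry.  Output columns ``region_a, region_b, strength`` with
    ``region_a < region_b``.
    """
    required = {"source", "target", "strength"}
    if not required <= set(tracer.columns):
        raise ValueError(f"tracer table must have columns {sorted(required)}")
    dup = tracer.duplicated(subset=["source", "target"])
    if dup.any():
        raise ValueError("tracer table has duplicate ordered pairs")
    acc: dict[tuple[str, str], list[float]] = {}
    for src, tgt, s in tracer[["source", "target", "strength"]].itertuples(
        index=False
    ):
        key = (src, tgt) if src <= tgt else (tgt, src)
        acc.setdefault(key, []).append(float(s))
    rows = [
        {"region_a": a, "region_b": b, "strength": float(np.mean(vals))}
        for (a, b), vals in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["region_a", "region_b", "strength"])


def tracer_concordance(
    dti_vector: SeedVector,
    tracer: pd.DataFrame,
    seed_region: str,
    region_mapping: Mapping[str, str | None] | None = None,
    symmetrize: bool = True,
) -> tuple[float, float]:
    """Spearman concordance between a diffusion fingerprint and tracer strengths.

    The tracer table is symmetrized (skippable for strength indices measured
    in one direction only), restricted to connections involving
    ``seed_region``, its region names mapped onto the diffusion atlas
    (many-to-one, aggregated by summation; regions mapping to ``None`` are
    dropped as unmappable), and the shared regions correlated with the
    diffusion vector.  Requires at least 3 shared regions.
    """
    if symmetrize:
        und = symmetrize_tracer(tracer)
        pairs = und[
            (und["region_a"] == seed_region) | (und["region_b"] == seed_region)
        ]
        partner = np.where(
            pairs["region_a"] == seed_region, pairs["region_b"], pairs["region_a"]
        )
        strengths = pd.Series(
            pairs["strength"].to_numpy(), index=partner, dtype=float
        )
    else:
        sub = tracer[
            (tracer["source"] == seed_region) | (tracer["target"] == seed_region)
        ]
        partner = np.where(
            sub["source"] == seed_region, sub["target"], sub["source"]
        )
        strengths = pd.Series(
            sub["strength"].to_numpy(), index=partner, dtype=float
        ).groupby(level=0).mean()

    if region_mapping is not None:
        mapped: dict[str, float] = {}
        for region, s in strengths.items():
            atlas = region_mapping.get(region, region)
            if atlas is None:
                continue  # unmappable region, dropped
            mapped[atlas] = mapped.get(atlas, 0.0) + s
        strengths = pd.Series(mapped, dtype=float)

    dti = pd.Series(dti_vector.strengths, index=dti_vector.target_labels)
    shared = [t for t in dti.index if t in strengths.index]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} regions shared between tracer and diffusion "
            "atlases; need at least 3"
        )
    rho, p = stats.spearmanr(dti[shared].to_numpy(), strengths[shared].to_numpy())
    return float(rho), float(p)
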