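"""Orchestration of the voxel-level and ROI-level analysis arms.

Each arm consumes per-species synthetic configurations (or pre-generated
objects), chains the stage modules in the study's order, writes tidy tables
and NIfTI volumes under an output directory, and stamps a manifest
recording the seed, configuration hash and the conventions in effect, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from mtplus import io
from mtplus.cross_species import (
    HomologyTable,
    cross_species_seed_correlation,
    project_to_common_space,
    tracer_concordance,
)
from mtplus.graph import (
    DEFAULT_SPARSITIES,
    WeightedNetwork,
    auc_table,
    normalize_total_strength,
    sparsity_sweep,
)
from mtplus.overlap import dice_pair, dice_third_order
from mtplus.roi import (
    fisher_z,
    group_average_connectome,
    normalize_by_node_size,
    seed_pattern_correlation,
    seed_vector,
    similarity_sets,
    top_fraction_union,
)
from mtplus.synthetic import (
    SEEDS,
    SyntheticConfig,
    generate_roi_connectomes,
    generate_tracer_table,
    generate_voxel_profiles,
    region_labels,
)
from mtplus.voxel import (
    binarize_profile,
    classify_mpm,
    group_average_profile,
    group_probability_map,
    overlap_fraction,
)

logger = logging.getLogger("mtplus")

SEED_PAIRS = tuple(combinations(SEEDS, 2))

# conventions in effect where the published procedure leaves a choice open;
# recorded in every run manifest for auditability
CONVENTIONS = {
    "mpm_tie_rule": "exact ties at the maximum are OVERLAP",
    "mpm_zero_rule": "all-zero voxels are UNCLASSIFIED, excluded from the "
    "overlap denominator",
    "node_volume_normalization": "w_ab = c_ab * 2 / (V_a + V_b)",
    "top_fraction_count": "ceil(fraction * n_candidates), ties by label",
    "metric_auc_rule": "trapezoid over the sparsity sweep",
    "sparsity_tie_break": "weight descending, then (label_a, label_b)",
}


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    output_dir: str = "mtplus_out"
    rng_seed: int = 0
    species: dict = field(
        default_factory=lambda: {"human": {"preset": "human_like"},
                                 "macaque": {"preset": "macaque_like"}}
    )
    fraction_sweep: tuple = (0.5,)
    sparsity_sweep: tuple = DEFAULT_SPARSITIES
    bonferroni_seed_pairs: int = 6
    bonferroni_cross_species: int = 3
    tracer_seed_region: str = "MT"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, sweep in (
            ("fraction_sweep", self.fraction_sweep),
            ("sparsity_sweep", self.sparsity_sweep),
        ):
            sweep = tuple(float(s) for s in sweep)
            if len(sweep) == 0 or any(not 0 < s <= 1 for s in sweep):
                raise ValueError(f"{name} must be a nonempty sequence in (0, 1]")
            if list(sweep) != sorted(sweep):
                raise ValueError(f"{name} must be ascending")
            setattr(self, name, sweep)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def synthetic_configs(self) -> dict[str, SyntheticConfig]:
        """Materialize one SyntheticConfig per species entry."""
        out = {}
        for i, (name, spec) in enumerate(sorted(self.species.items())):
            spec = dict(spec)
            preset = spec.pop("preset", "human_like")
            # distinct, reproducible per-species seed derived from the run seed
            spec.setdefault("rng_seed", (int(self.rng_seed) * 1000 + i) % (2**31))
            factory = getattr(SyntheticConfig, preset)
            out[name] = factory(**spec)
        return out


def _manifest(config: RunConfig, out_dir: Path, arm: str) -> None:
    from mtplus import __version__

    payload = asdict(config)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "arm": arm,
        "package_version": __version__,
        "rng_seed": config.rng_seed,
        "config": payload,
        "config_sha256": digest,
        "conventions": CONVENTIONS,
    }
    with open(out_dir / f"manifest_{arm}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def synthetic_homology(n_homologs: int = 27) -> HomologyTable:
    """Synthetic stand-in homology table for generated data.

    Maps the first ``n_homologs`` synthetic target regions of each species
    one-to-one onto shared homolog names, cycling the four lobes.
    """
    lobes = ("frontal", "parietal", "temporal", "occipital")
    rows = []
    for species in ("human", "macaque"):
        for k, label in enumerate(region_labels(n_homologs)):
            rows.append(
                {
                    "species": species,
                    "atlas_label": label,
                    "homolog": f"H{k + 1:02d}",
                    "lobe": lobes[k % 4],
                }
            )
    return HomologyTable(pd.DataFrame(rows))


def run_voxel_arm(config: RunConfig) -> dict:
    """Voxel-level arm: Dice tables, group maps, MPM and overlap fraction."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"dice": None, "overlap_fraction": {}, "mpm": {}}
    dice_rows = []

    for species, syn in config.synthetic_configs().items():
        if syn.n_subjects < 1:
            raise ValueError(f"species {species!r} has an empty subject list")
        profiles, gm_mask, wm_mask = generate_voxel_profiles(syn)
        logger.info("voxel arm: %s, %d subjects", species, len(profiles))

        for sid, per_seed in profiles.items():
            binary = {s: binarize_profile(p).mask for s, p in per_seed.items()}
            for tissue, mask in (("GM", gm_mask), ("WM", wm_mask)):
                for a, b in SEED_PAIRS:
                    dice_rows.append(
                        {
                            "species": species,
                            "subject": sid,
                            "tissue": tissue,
                            "comparison": f"{a}-{b}",
                            "coefficient": dice_pair(
                                binary[a], binary[b], mask=mask
                            ),
                        }
                    )
                dice_rows.append(
                    {
                        "species": species,
                        "subject": sid,
                        "tissue": tissue,
                        "comparison": "third_order",
                        "coefficient": dice_third_order(
                            *(binary[s] for s in SEEDS), mask=mask
                        ),
                    }
                )

        averaged = {}
        for seed in SEEDS:
            stack = [profiles[sid][seed] for sid in profiles]
            prob = group_probability_map([binarize_profile(p) for p in stack])
            io.save_volume(
                prob.fraction, out_dir / f"probmap_{species}_{seed}.nii.gz"
            )
            averaged[seed] = group_average_profile(stack)
            io.save_volume(
                averaged[seed], out_dir / f"groupavg_{species}_{seed}.nii.gz"
            )

        mpm = classify_mpm(averaged, wm_mask)
        io.save_mpm(mpm, out_dir / f"mpm_{species}.nii.gz")
        results["mpm"][species] = mpm
        results["overlap_fraction"][species] = overlap_fraction(mpm)
        io.save_volume(gm_mask, out_dir / f"gm_mask_{species}.nii.gz",
                       dtype=np.uint8)
        io.save_volume(wm_mask, out_dir / f"wm_mask_{species}.nii.gz",
                       dtype=np.uint8)

    dice = pd.DataFrame(dice_rows)
    dice.to_csv(out_dir / "dice.csv", index=False)
    pd.DataFrame(
        sorted(results["overlap_fraction"].items()),
        columns=["species", "overlap_percent"],
    ).to_csv(out_dir / "overlap_fraction.csv", index=False)
    results["dice"] = dice
    _manifest(config, out_dir, "voxel")
    return results


def run_roi_arm(
    config: RunConfig, homology: HomologyTable | None = None
) -> dict:
    """ROI-level arm: fingerprints, similarity sets, common space, tracer, graph."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"group": {}, "profiles": {}}

    corr_rows, sim_rows, graph_frames, auc_frames, tracer_rows = [], [], [], [], []

    for species, syn in config.synthetic_configs().items():
        raw_subjects, latent = generate_roi_connectomes(syn)
        normalized = [
            normalize_by_node_size(
                c.weights, c.node_volumes, c.labels, subject_id=c.subject_id
            )
            for c in raw_subjects
        ]
        group = group_average_connectome(normalized)
        io.save_connectome(group, out_dir / f"group_connectome_{species}.csv")
        latent.to_csv(out_dir / f"latent_truth_{species}.csv")
        results["group"][species] = group

        # seed fingerprints on the top-fraction target union, per fraction
        for fraction in config.fraction_sweep:
            targets = top_fraction_union(group, SEEDS, fraction)
            vectors = {s: seed_vector(group, s, targets) for s in SEEDS}
            for a, b in SEED_PAIRS:
                rho, p_adj = seed_pattern_correlation(
                    vectors[a], vectors[b], n_tests=config.bonferroni_seed_pairs
                )
                corr_rows.append(
                    {
                        "species": species,
                        "fraction": fraction,
                        "pair": f"{a}-{b}",
                        "rho": rho,
                        "p_bonferroni": p_adj,
                        "n_targets": len(targets),
                    }
                )

        # within/between-subject similarity sets at the default fraction
        targets = top_fraction_union(group, SEEDS, config.fraction_sweep[0])
        subj_vectors = {
            s: [seed_vector(c, s, targets) for c in normalized] for s in SEEDS
        }
        for a, b in SEED_PAIRS:
            sets = similarity_sets(subj_vectors[a], subj_vectors[b])
            for kind, values in (
                (f"{a}-{a}", sets.set_aa),
                (f"{b}-{b}", sets.set_bb),
                (f"{a}-{b}", sets.set_ab),
            ):
                for rho in values:
                    sim_rows.append(
                        {
                            "species": species,
                            "pair": f"{a}|{b}",
                            "set": kind,
                            "rho": rho,
                            "fisher_z": fisher_z(rho),
                        }
                    )

        # common-space projection
        hom = homology or synthetic_homology()
        profile = project_to_common_space(group, hom, species)
        results["profiles"][species] = profile
        profile.tidy(hom).to_csv(
            out_dir / f"common_space_{species}.csv", index=False
        )

        # tracer concordance against the group fingerprint
        tracer = generate_tracer_table(
            syn, group, seed_region=config.tracer_seed_region
        )
        tracer.to_csv(out_dir / f"tracer_{species}.csv", index=False)
        tracer_targets = [
            lab
            for lab in group.labels
            if lab not in SEEDS and group.row(config.tracer_seed_region)[lab] > 0
        ]
        dti_vec = seed_vector(group, config.tracer_seed_region, tracer_targets)
        rho, p = tracer_concordance(dti_vec, tracer, config.tracer_seed_region)
        tracer_rows.append(
            {"species": species, "seed": config.tracer_seed_region,
             "rho": rho, "p": p, "n_regions": len(tracer_targets)}
        )

        # tool-use style subnetwork: the 3 seeds plus the 7 strongest-labeled
        # synthetic targets, per subject, weighted nodal metrics + AUC
        tool_nodes = list(SEEDS) + region_labels(7)
        for conn in normalized:
            idx = [conn.index(n) for n in tool_nodes]
            sub = conn.weights[np.ix_(idx, idx)]
            net = normalize_total_strength(WeightedNetwork(sub, tool_nodes))
            sweep = sparsity_sweep(net, config.sparsity_sweep)
            sweep.insert(0, "species", species)
            sweep.insert(1, "subject", conn.subject_id)
            graph_frames.append(sweep)
            aucs = auc_table(net, config.sparsity_sweep).rename_axis("node")
            aucs = aucs.reset_index()
            aucs.insert(0, "species", species)
            aucs.insert(1, "subject", conn.subject_id)
            auc_frames.append(aucs)

    results["seed_correlations"] = pd.DataFrame(corr_rows)
    results["similarity"] = pd.DataFrame(sim_rows)
    results["tracer"] = pd.DataFrame(tracer_rows)
    results["graph"] = pd.concat(graph_frames, ignore_index=True)
    results["auc"] = pd.concat(auc_frames, ignore_index=True)
    results["seed_correlations"].to_csv(
        out_dir / "seed_pattern_correlations.csv", index=False
    )
    results["similarity"].to_csv(out_dir / "similarity_sets.csv", index=False)
    results["tracer"].to_csv(out_dir / "tracer_concordance.csv", index=False)
    results["graph"].to_csv(out_dir / "graph_metrics.csv", index=False)
    results["auc"].to_csv(out_dir / "graph_auc.csv", index=False)

    # cross-species fingerprint comparison when both species are present
    species_names = sorted(results["profiles"])
    if len(species_names) >= 2:
        cross_rows = []
        for sa, sb in combinations(species_names, 2):
            for seed in SEEDS:
                rho, p_adj = cross_species_seed_correlation(
                    results["profiles"][sa],
                    results["profiles"][sb],
                    seed,
                    n_tests=config.bonferroni_cross_species,
                )
                cross_rows.append(
                    {"species_a": sa, "species_b": sb, "seed": seed,
                     "rho": rho, "p_bonferroni": p_adj}
                )
        results["cross_species"] = pd.DataFrame(cross_rows)
        results["cross_species"].to_csv(
            out_dir / "cross_species_correlations.csv", index=False
        )
    else:
        logger.info("single species: cross-species comparison skipped")
        results["cross_species"] = None

    _manifest(config, out_dir, "roi")
    return results


def run_all(config: RunConfig, homology: HomologyTable | None = None) -> dict:
    """Both arms; the study's full synthetic experiment."""
    return {
        "voxel": run_voxel_arm(config),
        "roi": run_roi_arm(config, homology=homology),
    }
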