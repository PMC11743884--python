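"""Common-space projection, cross-species fingerprints, tracer concordance."""

import numpy as np
import pandas as pd
import pytest

from mtplus.cross_species import (
    CommonSpaceProfile,
    HomologyTable,
    cross_species_seed_correlation,
    project_to_common_space,
    symmetrize_tracer,
    tracer_concordance,
)
from mtplus.pipeline import synthetic_homology
from mtplus.roi import ConnectomeMatrix, SeedVector
from oracles import spearman_rho


def small_homology():
    rows = []
    for species in ("human", "macaque"):
        rows += [
            {"species": species, "atlas_label": f"{species[0]}A", "homolog": "H1",
             "lobe": "frontal"},
            {"species": species, "atlas_label": f"{species[0]}B", "homolog": "H2",
             "lobe": "parietal"},
            {"species": species, "atlas_label": f"{species[0]}B2", "homolog": "H2",
             "lobe": "parietal"},
            {"species": species, "atlas_label": f"{species[0]}C", "homolog": "H3",
             "lobe": "temporal"},
        ]
    return HomologyTable(pd.DataFrame(rows))


def conn_for(labels, seed_weights):
    """Connectome with given seed->target weights, zero elsewhere."""
    labels = ("MST", "MT", "FST") + tuple(labels)
    n = len(labels)
    w = np.zeros((n, n))
    for (seed, tgt), val in seed_weights.items():
        i, j = labels.index(seed), labels.index(tgt)
        w[i, j] = w[j, i] = val
    return ConnectomeMatrix(w, labels)


class TestHomologyTable:
    def test_missing_homolog_for_one_species_rejected(self):
        tab = small_homology().table
        with pytest.raises(ValueError):
            HomologyTable(tab[~((tab.species == "human") & (tab.homolog == "H3"))])

    def test_packaged_default_has_27_homologs_both_species(self):
        default = HomologyTable.default()
        assert len(default.homologs) == 27
        for species in ("human", "macaque"):
            assert len(default.mapping_for(species)) == 27

    def test_lobe_lookup(self):
        assert small_homology().lobe_of("H2") == "parietal"


class TestProjection:
    def test_many_to_one_aggregates_by_sum(self):
        conn = conn_for(
            ["hA", "hB", "hB2", "hC"],
            {("MST", "hB"): 1.0, ("MST", "hB2"): 2.0, ("MST", "hA"): 5.0},
        )
        prof = project_to_common_space(conn, small_homology(), "human")
        assert prof.strengths.loc["MST", "H2"] == pytest.approx(3.0)
        assert prof.strengths.loc["MST", "H1"] == pytest.approx(5.0)

    def test_one_to_one_is_submatrix_extraction(self):
        conn = conn_for(["hA", "hB", "hB2", "hC"], {("MT", "hC"): 4.0})
        prof = project_to_common_space(conn, small_homology(), "human")
        assert prof.strengths.loc["MT", "H3"] == pytest.approx(4.0)

    def test_equal_strengths_get_average_joint_ranks(self):
        conn = conn_for(["hA", "hB", "hB2", "hC"], {})
        prof = project_to_common_space(conn, small_homology(), "human")
        # all 9 strengths are 0 -> every joint rank is the mean rank 5
        assert np.allclose(prof.joint_ranks.to_numpy(), 5.0)

    def test_joint_ranks_are_a_ranking_of_all_entries(self):
        rng = np.random.default_rng(0)
        weights = {
            (s, t): rng.random()
            for s in ("MST", "MT", "FST")
            for t in ("hA", "hB", "hB2", "hC")
        }
        conn = conn_for(["hA", "hB", "hB2", "hC"], weights)
        prof = project_to_common_space(conn, small_homology(), "human")
        ranks = np.sort(prof.joint_ranks.to_numpy().ravel())
        assert np.allclose(ranks, np.arange(1, 10))

    def test_missing_atlas_label_rejected(self):
        conn = conn_for(["hA", "hB", "hC"], {})  # hB2 absent
        with pytest.raises(ValueError):
            project_to_common_space(conn, small_homology(), "human")


class TestCrossSpeciesCorrelation:
    def profile(self, species, values):
        homs = [f"H{i}" for i in range(len(values))]
        df = pd.DataFrame(
            np.tile(values, (3, 1)), index=["MST", "MT", "FST"], columns=homs
        )
        from scipy.stats import rankdata

        ranks = pd.DataFrame(
            rankdata(df.to_numpy(), axis=None).reshape(df.shape),
            index=df.index, columns=df.columns,
        )
        return CommonSpaceProfile(species, df, ranks)

    def test_identical_profiles_give_one(self):
        a = self.profile("human", [1.0, 2.0, 3.0, 4.0, 5.0])
        b = self.profile("macaque", [1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = cross_species_seed_correlation(a, b, "MST")
        assert rho == pytest.approx(1.0)

    def test_reversed_profile_gives_minus_one(self):
        a = self.profile("human", [1.0, 2.0, 3.0, 4.0, 5.0])
        b = self.profile("macaque", [5.0, 4.0, 3.0, 2.0, 1.0])
        rho, _ = cross_species_seed_correlation(a, b, "MST")
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_oracle_and_is_symmetric(self):
        x = [0.3, 1.9, 0.2, 4.4, 2.5]
        y = [1.1, 0.4, 3.3, 2.0, 2.0]
        a, b = self.profile("human", x), self.profile("macaque", y)
        rho_ab, p_ab = cross_species_seed_correlation(a, b, "MT")
        rho_ba, p_ba = cross_species_seed_correlation(b, a, "MT")
        assert rho_ab == pytest.approx(spearman_rho(x, y))
        assert (rho_ab, p_ab) == (rho_ba, p_ba)

    def test_misaligned_homologs_rejected(self):
        a = self.profile("human", [1.0, 2.0, 3.0])
        b = self.profile("macaque", [1.0, 2.0, 3.0])
        b.strengths.columns = ["H2", "H0", "H1"]
        with pytest.raises(ValueError):
            cross_species_seed_correlation(a, b, "MST")


class TestTracer:
    def test_bidirectional_mean(self):
        tab = pd.DataFrame(
            [("A", "B", 2.0), ("B", "A", 4.0)],
            columns=["source", "target", "strength"],
        )
        und = symmetrize_tracer(tab)
        assert und.loc[0, "strength"] == pytest.approx(3.0)

    def test_single_direction_kept_as_is(self):
        tab = pd.DataFrame(
            [("A", "B", 5.0)], columns=["source", "target", "strength"]
        )
        assert symmetrize_tracer(tab).loc[0, "strength"] == pytest.approx(5.0)

    def test_idempotent_on_symmetric_tables(self):
        tab = pd.DataFrame(
            [("A", "B", 3.0), ("B", "A", 3.0), ("A", "C", 1.0), ("C", "A", 1.0)],
            columns=["source", "target", "strength"],
        )
        und = symmetrize_tracer(tab)
        back = pd.DataFrame(
            {"source": und.region_a, "target": und.region_b,
             "strength": und.strength}
        )
        assert symmetrize_tracer(back).strength.tolist() == und.strength.tolist()

    def test_duplicate_ordered_pairs_rejected(self):
        tab = pd.DataFrame(
            [("A", "B", 1.0), ("A", "B", 2.0)],
            columns=["source", "target", "strength"],
        )
        with pytest.raises(ValueError):
            symmetrize_tracer(tab)


class TestTracerConcordance:
    def seed_vec(self, targets, values):
        return SeedVector("MT", tuple(targets), np.asarray(values, float))

    def tracer_for(self, strengths: dict, seed="MT"):
        rows = []
        for region, s in strengths.items():
            rows.append((seed, region, s))
            rows.append((region, seed, s))
        return pd.DataFrame(rows, columns=["source", "target", "strength"])

    def test_monotone_transform_gives_one(self):
        targets = ["T1", "T2", "T3", "T4", "T5"]
        dti = self.seed_vec(targets, [0.1, 0.5, 0.2, 0.9, 0.4])
        tracer = self.tracer_for({t: np.exp(v) for t, v in zip(targets, dti.strengths)})
        rho, _ = tracer_concordance(dti, tracer, "MT")
        assert rho == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        targets = ["T1", "T2", "T3", "T4"]
        dti = self.seed_vec(targets, [1.0, 2.0, 3.0, 4.0])
        tracer = self.tracer_for(dict(zip(targets, [4.0, 3.0, 2.0, 1.0])))
        rho, _ = tracer_concordance(dti, tracer, "MT")
        assert rho == pytest.approx(-1.0)

    def test_noisy_tracer_matches_rank_oracle(self):
        rng = np.random.default_rng(42)
        targets = [f"T{i}" for i in range(30)]
        dti_vals = rng.lognormal(size=30)
        dti = self.seed_vec(targets, dti_vals)
        out_noise = np.exp(0.4 * rng.standard_normal(30))
        in_noise = np.exp(0.4 * rng.standard_normal(30))
        rows = []
        for t, v, no, ni in zip(targets, dti_vals, out_noise, in_noise):
            rows.append(("MT", t, v * no))
            rows.append((t, "MT", v * ni))
        tracer = pd.DataFrame(rows, columns=["source", "target", "strength"])
        rho, _ = tracer_concordance(dti, tracer, "MT")
        expected = spearman_rho(dti_vals, (dti_vals * out_noise + dti_vals * in_noise) / 2)
        assert rho == pytest.approx(expected)

    def test_region_mapping_aggregates_and_drops_unmappable(self):
        # tracer atlas regions a1, a2 both map to atlas T1; x is unmappable
        dti = self.seed_vec(["T1", "T2", "T3"], [5.0, 1.0, 3.0])
        tracer = self.tracer_for({"a1": 2.0, "a2": 2.0, "T2": 1.0, "T3": 3.0,
                                  "x": 99.0})
        mapping = {"a1": "T1", "a2": "T1", "T2": "T2", "T3": "T3", "x": None}
        rho, _ = tracer_concordance(dti, tracer, "MT", region_mapping=mapping)
        # aggregated tracer: T1=4, T2=1, T3=3 -> same ranking as DTI
        assert rho == pytest.approx(1.0)

    def test_one_directional_mode(self):
        targets = ["T1", "T2", "T3"]
        dti = self.seed_vec(targets, [1.0, 2.0, 3.0])
        rows = [("MT", t, v) for t, v in zip(targets, [1.0, 2.0, 3.0])]
        tracer = pd.DataFrame(rows, columns=["source", "target", "strength"])
        rho, _ = tracer_concordance(dti, tracer, "MT", symmetrize=False)
        assert rho == pytest.approx(1.0)

    def test_too_few_shared_regions_rejected(self):
        dti = self.seed_vec(["T1", "T2", "T3"], [1.0, 2.0, 3.0])
        tracer = self.tracer_for({"T1": 1.0, "Z": 2.0})
        with pytest.raises(ValueError):
            tracer_concordance(dti, tracer, "MT")


def test_synthetic_homology_covers_both_species():
    hom = synthetic_homology(27)
    assert len(hom.homologs) == 27
    assert set(hom.table.species) == {"human", "macaque"}
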