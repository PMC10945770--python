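"""Synthetic-data generators: determinism, scaling laws, known expectations."""

import json
from pathlib import Path

import numpy as np
import pytest

import evorate as ev


class TestYule:
    def test_two_taxa_is_a_cherry(self):
        tree = ev.simulate_yule_tree(2, 1.0, seed=1)
        assert len(ev.leaf_labels(tree)) == 2
        assert tree.seed_node.num_child_nodes() == 2

    def test_fixed_seed_reproducible(self):
        a = ev.write_newick(ev.simulate_yule_tree(12, 1.0, seed=5))
        b = ev.write_newick(ev.simulate_yule_tree(12, 1.0, seed=5))
        assert a == b

    def test_trees_are_ultrametric(self):
        depths = list(ev.root_to_tip(ev.simulate_yule_tree(25, 2.0, seed=6)).values())
        assert np.ptp(depths) < 1e-9

    def test_expected_depth_matches_closed_form(self):
        # depth = sum of Exp(k·λ) waits for k = 2..n, so
        # E[depth] = (1/λ) Σ_{k=2..n} 1/k
        n, lam = 8, 1.0
        expected = sum(1 / k for k in range(2, n + 1)) / lam
        depths = [
            next(iter(ev.root_to_tip(ev.simulate_yule_tree(n, lam, seed=s)).values()))
            for s in range(1000)
        ]
        se = np.std(depths, ddof=1) / np.sqrt(len(depths))
        assert abs(np.mean(depths) - expected) < 4 * se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ev.simulate_yule_tree(1, 1.0, seed=1)
        with pytest.raises(ValueError):
            ev.simulate_yule_tree(5, -1.0, seed=1)
        with pytest.raises(ValueError):
            ev.simulate_yule_tree(5, 1.0)


class TestOrthogroupCohort:
    def test_zero_variance_rate_reproduces_species_tree(self):
        species = ev.simulate_yule_tree(6, 1.0, seed=10)
        trees, smap, rates = ev.simulate_orthogroup_cohort(
            species, 3, rate_mu=0.0, rate_sigma=0.0, seed=11
        )
        assert np.allclose(rates, 1.0)
        base = ev.patristic_matrix(species)
        for og_id, tree in trees.items():
            mat = ev.patristic_matrix(tree)
            mat.index = [smap[g] for g in mat.index]
            mat.columns = [smap[g] for g in mat.columns]
            mat = mat.loc[base.index, base.columns]
            np.testing.assert_allclose(mat.values, base.values, rtol=1e-9)

    def test_fixed_rate_two_doubles_distances(self):
        species = ev.simulate_yule_tree(6, 1.0, seed=10)
        trees, smap, _ = ev.simulate_orthogroup_cohort(
            species, 2, rate_mu=np.log(2.0), rate_sigma=0.0, seed=12
        )
        base = ev.patristic_matrix(species)
        mat = ev.patristic_matrix(next(iter(trees.values())))
        mat.index = [smap[g] for g in mat.index]
        mat.columns = [smap[g] for g in mat.columns]
        np.testing.assert_allclose(
            mat.loc[base.index, base.columns].values, 2 * base.values, rtol=1e-9
        )

    def test_gene_labels_carry_species(self):
        species = ev.simulate_yule_tree(4, 1.0, seed=13)
        trees, smap, _ = ev.simulate_orthogroup_cohort(species, 2, seed=14)
        for og_id, tree in trees.items():
            for leaf in ev.leaf_labels(tree):
                assert leaf.split("|")[0] == smap[leaf]

    def test_deterministic_given_seed(self):
        species = ev.simulate_yule_tree(5, 1.0, seed=15)
        a = ev.simulate_orthogroup_cohort(species, 4, seed=16)
        b = ev.simulate_orthogroup_cohort(species, 4, seed=16)
        assert [ev.write_newick(t) for t in a[0].values()] == [
            ev.write_newick(t) for t in b[0].values()
        ]


class TestMulticopyFamily:
    def test_all_single_copy_identity(self):
        species = ev.simulate_yule_tree(6, 1.0, seed=20)
        tree, smap = ev.simulate_multicopy_family(species, {1: 1.0}, seed=21)
        assert ev.tree_total_length(tree) == pytest.approx(
            ev.tree_total_length(species)
        )
        assert sorted(smap) == sorted(ev.leaf_labels(species))

    def test_zero_divergence_copies_give_degenerate_bootstrap(self):
        species = ev.simulate_yule_tree(5, 1.0, seed=22)
        tree, smap = ev.simulate_multicopy_family(species, {2: 1.0}, 0.0, seed=23)
        out = ev.stratified_bootstrap_tree_length(tree, smap, 100, seed=24)
        assert out.sd == pytest.approx(0.0, abs=1e-12)

    def test_two_outcome_family_bootstrap_matches_enumeration(self):
        species = ev.read_newick("(A:1.0,B:1.0);")
        tree, smap = ev.simulate_multicopy_family(
            species, {"A": 2, "B": 1}, within_species_divergence=0.5, seed=25
        )
        pendants = sorted(
            lf.edge.length for lf in tree.leaf_node_iter() if smap[_lab(lf)] == "A"
        )
        expected_mean = np.mean(
            [ev.tree_total_length(tree) - pendants[0], ev.tree_total_length(tree) - pendants[1]]
        )
        out = ev.stratified_bootstrap_tree_length(tree, smap, 4000, seed=26)
        spread = abs(pendants[1] - pendants[0])
        assert abs(out.mean - expected_mean) < 3 * (spread / 2) / np.sqrt(4000)

    def test_copy_count_distribution_respected(self):
        species = ev.simulate_yule_tree(50, 1.0, seed=27)
        tree, smap = ev.simulate_multicopy_family(species, {3: 1.0}, seed=28)
        counts = {}
        for gene, sp in smap.items():
            counts[sp] = counts.get(sp, 0) + 1
        assert set(counts.values()) == {3}


def _lab(leaf):
    return leaf.taxon.label if leaf.taxon else leaf.label


class TestDirectionalTraits:
    def test_zero_noise_exact_recovery(self):
        tree = ev.jitter_branch_lengths(
            ev.simulate_yule_tree(30, 1.0, seed=30), 0.4, seed=31
        )
        traits = ev.simulate_directional_traits(tree, 81.1, 20.0, 0.0, seed=32)
        rtt = ev.root_to_tip(tree)
        species = sorted(rtt)
        reg = ev.fit_ols([rtt[s] for s in species], traits.loc[species, "trait"])
        assert reg.slope == pytest.approx(20.0)
        assert reg.intercept == pytest.approx(81.1)
        assert reg.r_squared == pytest.approx(1.0)

    def test_null_slope_centered_on_zero(self):
        tree = ev.jitter_branch_lengths(
            ev.simulate_yule_tree(40, 1.0, seed=33), 0.4, seed=34
        )
        rtt = ev.root_to_tip(tree)
        species = sorted(rtt)
        slopes = []
        for s in range(200):
            traits = ev.simulate_directional_traits(tree, 81.1, 0.0, 5.0, seed=100 + s)
            slopes.append(
                ev.fit_ols([rtt[sp] for sp in species], traits.loc[species, "trait"]).slope
            )
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se

    def test_deterministic_given_seed(self):
        tree = ev.simulate_yule_tree(10, 1.0, seed=35)
        a = ev.simulate_directional_traits(tree, 1.0, 2.0, 0.5, seed=36)
        b = ev.simulate_directional_traits(tree, 1.0, 2.0, 0.5, seed=36)
        assert a.equals(b)


class TestScaling:
    def test_scaling_tree_scales_all_metrics(self):
        species = ev.simulate_yule_tree(10, 1.0, seed=40)
        scaled_trees, smap, _ = ev.simulate_orthogroup_cohort(
            species, 1, rate_mu=np.log(3.0), rate_sigma=0.0, seed=41
        )
        scaled = next(iter(scaled_trees.values()))
        assert ev.tree_total_length(scaled) == pytest.approx(
            3 * ev.tree_total_length(species), rel=1e-9
        )
        base_rtt = ev.root_to_tip(species)
        for gene, d in ev.root_to_tip(scaled).items():
            assert d == pytest.approx(3 * base_rtt[smap[gene]], rel=1e-9)


class TestFixtureBundle:
    def test_bundle_complete_and_reproducible(self, tmp_path):
        config = ev.SimulationConfig(seed=50, n_taxa=8, n_orthogroups=6)
        m1 = ev.make_fixture_bundle(config, tmp_path / "one")
        m2 = ev.make_fixture_bundle(config, tmp_path / "two")
        for name in m1["files"]:
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes(), name
        assert m1["n_orthogroups"] == 6

    def test_bundle_loadable_by_pipeline(self, tmp_path):
        config = ev.SimulationConfig(
            seed=51, n_taxa=8, n_orthogroups=5, noise_sd=0.0
        )
        out = tmp_path / "bundle"
        ev.make_fixture_bundle(config, out)
        tree = ev.read_newick(out / "focal_gene_tree.nwk")
        traits = ev.read_trait_table(out / "traits.tsv")
        result = ev.pipeline_kinetics(tree, traits, n_sites=500)
        assert result["regressions"].loc["trait", "r2_percent"] == pytest.approx(100.0)
        assert result["regressions"].loc["trait", "intercept"] == pytest.approx(
            config.intercept
        )
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["config"]["seed"] == 51
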