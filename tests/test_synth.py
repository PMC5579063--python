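"""Synthetic-world generator: determinism, planted structure, and the
ground-truth contract."""

import dataclasses

import numpy as np
import pytest

from drugfams.core import classify_interactions, build_profiles, InteractionClass
from drugfams.network import matrix_similarity
from drugfams.synth import SyntheticConfig, generate_world


class TestDeterminism:
    def test_same_config_and_seed_byte_identical(self, tmp_path, small_world):
        cfg = small_world.config
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        generate_world(cfg).write(a_dir)
        generate_world(cfg).write(b_dir)
        for f in sorted(a_dir.iterdir()):
            assert f.read_bytes() == (b_dir / f.name).read_bytes(), f.name

    def test_different_seeds_differ(self):
        w1 = generate_world(SyntheticConfig(n_proteins=100, n_families=8, n_drugs=10, seed=1))
        w2 = generate_world(SyntheticConfig(n_proteins=100, n_families=8, n_drugs=10, seed=2))
        assert w1.activities != w2.activities


class TestPlantedTargets:
    def test_full_coherence_single_family(self):
        cfg = SyntheticConfig(n_proteins=100, n_families=8, n_drugs=6,
                              frac_coherent_drugs=1.0, coherent_fraction=1.0,
                              targets_per_drug=(4, 6), seed=3)
        w = generate_world(cfg)
        profiles = build_profiles(
            classify_interactions(w.activities), w.family_table
        )
        for drug, home in w.truth.home_family.items():
            assert home is not None
            assert profiles[drug].targets <= w.family_table.families[home]

    def test_within_family_fraction_matches_binomial_oracle(self):
        """Across a 200-drug world the mean within-home-family target
        fraction should sit within 3 standard errors of coherent_fraction
        (each drug draws round(c*k) of k targets from home)."""
        cfg = SyntheticConfig(n_drugs=200, seed=4)
        w = generate_world(cfg)
        fracs = []
        profiles = build_profiles(classify_interactions(w.activities), w.family_table)
        for drug, home in w.truth.home_family.items():
            if home is None:
                continue
            t = profiles[drug].targets
            fracs.append(len(t & w.family_table.families[home]) / len(t))
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        # rounding of n_home = round(c*k) biases each drug by at most 0.5/k
        assert abs(fracs.mean() - cfg.coherent_fraction) <= 3 * se + 0.5 / cfg.targets_per_drug[0]

    def test_infeasible_config_raises(self):
        cfg = SyntheticConfig(n_proteins=60, n_families=20, module_size_cap=3,
                              targets_per_drug=(12, 12), coherent_fraction=1.0,
                              seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_world(cfg)

    def test_activity_classes_cover_all_three(self, small_world):
        classes = set(classify_interactions(small_world.activities).values())
        assert classes == {InteractionClass.TARGET, InteractionClass.OFF_TARGET,
                           InteractionClass.UNCLASSIFIED}


class TestPlantedNetwork:
    def test_no_inter_module_edges_when_p_between_zero(self):
        cfg = SyntheticConfig(n_proteins=120, n_families=10, n_drugs=8,
                              p_between=0.0, target_hub_degree=0, seed=5)
        w = generate_world(cfg)
        for u, v in w.network.graph.edges:
            assert w.truth.module_of.get(u) == w.truth.module_of.get(v)

    def test_null_config_modules_look_random(self):
        """With p_within = p_between and identical weight laws the planted
        modules carry no signal: their matrix similarity is statistically
        indistinguishable from size-matched random sets."""
        cfg = SyntheticConfig(n_proteins=120, n_families=10, n_drugs=8,
                              p_within=0.1, p_between=0.1,
                              w_within=(2.0, 2.0), w_between=(2.0, 2.0),
                              target_hub_degree=0, seed=6)
        w = generate_world(cfg)
        rng = np.random.default_rng(6)
        nodes = sorted(w.network.nodes)
        wins = 0
        trials = 0
        for mod in sorted(w.truth.module_families):
            core = sorted(p for p, m in w.truth.module_of.items() if m == mod)
            s = matrix_similarity(core, w.network)
            if s.value is None:
                continue
            null = [
                matrix_similarity(
                    rng.choice(nodes, size=len(core), replace=False), w.network,
                    restrict_to_network=False,
                ).value
                for _ in range(30)
            ]
            trials += 1
            if s.value > np.quantile(null, 0.95):
                wins += 1
        assert trials >= 3
        assert wins <= max(1, 0.35 * trials)  # no systematic excess

    def test_default_modules_beat_random_sets(self, world):
        rng = np.random.default_rng(7)
        nodes = sorted(world.network.nodes)
        wins, total = 0, 0
        for mod in sorted(world.truth.module_families):
            core = sorted(p for p, m in world.truth.module_of.items() if m == mod)
            s = matrix_similarity(core, world.network)
            if s.value is None:
                continue
            for _ in range(8):
                total += 1
                r = matrix_similarity(
                    rng.choice(nodes, size=len(core), replace=False), world.network,
                    restrict_to_network=False,
                ).value
                if s.value > r:
                    wins += 1
        assert wins / total >= 0.95


class TestSideEffectPlanting:
    def test_counts_nonnegative_and_poisson_scaled(self, world):
        counts = world.side_effects.drug_counts
        assert all(c >= 0 for c in counts.values())
        lam_max = world.config.sidefx_base + world.config.sidefx_dispersion_gain
        assert np.mean(list(counts.values())) < lam_max

    def test_dispersion_gain_strengthens_negative_trend(self):
        """Monte-Carlo trend: raising sidefx_dispersion_gain makes the
        correlation between target clustering and side-effect count more
        negative."""
        mean_r = []
        for gain in (0.0, 10.0, 40.0):
            rs = []
            for seed in range(4):
                cfg = SyntheticConfig(n_proteins=150, n_families=12, n_drugs=40,
                                      sidefx_dispersion_gain=gain, seed=100 + seed)
                w = generate_world(cfg)
                x = [w.truth.dispersion[d] for d in sorted(w.truth.dispersion)]
                y = [w.side_effects.drug_counts[d] for d in sorted(w.truth.dispersion)]
                rs.append(np.corrcoef(x, y)[0, 1])
            mean_r.append(np.mean(rs))
        assert mean_r[0] > mean_r[1] > mean_r[2]
        assert mean_r[2] < -0.5


class TestGroundTruthContract:
    def test_truth_consistent_with_tables(self, small_world):
        w = small_world
        # every home family exists and is a module family
        for home in w.truth.home_family.values():
            if home is not None:
                assert home in w.family_table.families
                assert home in w.truth.module_families
        # module assignment agrees with membership
        for p, m in w.truth.module_of.items():
            assert p in w.family_table.families[m]
        # per-drug dispersion is reported for every drug
        assert set(w.truth.dispersion) == set(w.truth.home_family)

    def test_written_bundle_loads_back(self, tmp_path, small_world):
        from drugfams.core import (
            read_activity_table, read_family_table, read_side_effects,
        )
        from drugfams.network import read_network
        from drugfams.similarity import read_fingerprints

        paths = small_world.write(tmp_path / "bundle")
        assert read_activity_table(paths["activities"]) == small_world.activities
        ft = read_family_table(paths["families"])
        assert ft.families == small_world.family_table.families
        net = read_network(paths["network"])
        assert net.graph.number_of_edges() == small_world.network.graph.number_of_edges()
        fps = read_fingerprints(paths["fingerprints"])
        assert fps == small_world.fingerprints
        se = read_side_effects(paths["protein_side_effects"], paths["drug_side_effects"])
        assert se.protein_flags == small_world.side_effects.protein_flags
        assert se.drug_counts == small_world.side_effects.drug_counts
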