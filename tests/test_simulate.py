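"""Synthetic-data generators: process expectations, filters,
reproducibility."""

import math

import numpy as np
import pytest

from tipdating.simulate import (
    SimulationConfig, SimulationError, assign_age_windows,
    generate_tooth_meshes, simulate_biogeography, simulate_characters,
    simulate_dataset, simulate_dna, simulate_fbd_tree,
)
from tipdating.treemodel import TimeTree


class TestFbdTree:
    def test_no_fossils_without_fossilization(self):
        cfg = SimulationConfig(speciation=0.4, extinction=0.1,
                               fossilization=0.0, origin_age=10.0)
        for seed in range(5):
            tree, truth = simulate_fbd_tree(cfg, seed=seed)
            assert truth["n_fossil"] == 0
            assert all(t.age == 0 for t in tree.tips)

    def test_yule_expected_tip_count(self):
        lam, t = 0.3, 6.0
        cfg = SimulationConfig(speciation=lam, extinction=0.0,
                               fossilization=0.0, origin_age=t, rho=1.0)
        counts = [simulate_fbd_tree(cfg, seed=s, min_tips=1)[1]
                  ["n_extant"] for s in range(400)]
        expected = math.exp(lam * t)
        se = np.std(counts) / math.sqrt(len(counts))
        # conditioning on >=1 sampled tip slightly inflates the mean;
        # with exp(lam*t) ~ 6 the effect is < se here
        assert abs(np.mean(counts) - expected) < 4 * se + 0.3

    def test_rho_thinning(self):
        cfg_full = SimulationConfig(speciation=0.35, extinction=0.0,
                                    fossilization=0.0, origin_age=8.0,
                                    rho=1.0)
        cfg_half = SimulationConfig(speciation=0.35, extinction=0.0,
                                    fossilization=0.0, origin_age=8.0,
                                    rho=0.5)
        full = [simulate_fbd_tree(cfg_full, seed=s, min_tips=1)[1]
                ["n_extant"] for s in range(300)]
        half = [simulate_fbd_tree(cfg_half, seed=s, min_tips=1)[1]
                ["n_extant"] for s in range(300)]
        ratio = np.mean(half) / np.mean(full)
        assert 0.4 < ratio < 0.65

    def test_total_extinction_raises(self):
        cfg = SimulationConfig(speciation=0.01, extinction=5.0,
                               fossilization=0.0, origin_age=50.0)
        with pytest.raises(SimulationError):
            simulate_fbd_tree(cfg, seed=1, max_tries=5)

    def test_fossils_are_terminal_dated_tips(self):
        cfg = SimulationConfig(speciation=0.3, extinction=0.1,
                               fossilization=0.1, origin_age=12.0)
        tree, truth = simulate_fbd_tree(cfg, seed=7)
        tree.validate()
        fossil_tips = [t for t in tree.tips if t.age > 0]
        assert len(fossil_tips) == truth["n_fossil"]


@pytest.fixture(scope="module")
def char_tree():
    return TimeTree.from_newick("((A:2,B:2):2,(C:3,D:3):1);")


class TestCharacters:
    def test_variable_only_filter(self, char_tree):
        m = simulate_characters(char_tree, 50, k=2, clock_rate=0.05,
                                variable_only=True, seed=0)
        for j in range(m.n_chars):
            states = {next(iter(c)) for c in m.column(j)}
            assert len(states) >= 2

    def test_long_branch_stationarity(self):
        t = TimeTree.from_newick("((A:500,B:500):100,(C:550,D:550):50);")
        m = simulate_characters(t, 600, k=3, clock_rate=1.0,
                                variable_only=False, seed=1)
        flat = [next(iter(m.cells[i][j])) for i in range(4)
                for j in range(600)]
        freqs = np.bincount(flat, minlength=3) / len(flat)
        assert np.allclose(freqs, 1 / 3, atol=0.03)

    def test_ordered_simulation_never_jumps(self):
        # a star-like tree with many short branches approximates a
        # densely sampled path: adjacent-state moves only
        t = TimeTree.from_newick(
            "((A:0.05,B:0.05):0.05,(C:0.08,D:0.08):0.02);")
        m = simulate_characters(t, 400, k=4, ordered=True, clock_rate=1.0,
                                variable_only=False, seed=2)
        for j in range(m.n_chars):
            states = sorted(next(iter(c)) for c in m.column(j))
            # with tiny branches, multi-step transitions are vanishingly
            # rare; the observed state span stays tight
            assert states[-1] - states[0] <= 2


class TestDna:
    def test_uniform_stationarity(self):
        t = TimeTree.from_newick("((A:300,B:300):50,(C:330,D:330):20);")
        cfg = SimulationConfig(n_sites=4000, n_subsets=1, clock_rate=1.0,
                               dna_gamma_shape=10.0)
        mol, truth = simulate_dna(t, cfg, seed=3,
                                  exchangeabilities=np.ones(6),
                                  base_freqs=np.full(4, 0.25))
        freqs = np.bincount(mol.sites.ravel(), minlength=5)[:4]
        freqs = freqs / freqs.sum()
        assert np.allclose(freqs, 0.25, atol=0.02)

    def test_full_invariance(self):
        t = TimeTree.from_newick("((A:2,B:2):2,C:4);")
        cfg = SimulationConfig(n_sites=300, n_subsets=1, p_invariant=1.0,
                               clock_rate=0.5)
        mol, _ = simulate_dna(t, cfg, seed=4)
        assert all(len(set(mol.sites[:, j])) == 1
                   for j in range(mol.n_sites))

    def test_subset_structure(self):
        t = TimeTree.from_newick("((A:2,B:2):2,C:4);")
        cfg = SimulationConfig(n_sites=900, n_subsets=3)
        mol, truth = simulate_dna(t, cfg, seed=5)
        assert mol.n_subsets == 3
        assert len(mol.subset_sites(0)) == 300
        assert set(truth) == {0, 1, 2}


class TestAgeWindows:
    def test_truth_inside_window_and_extant_zero(self):
        cfg = SimulationConfig(speciation=0.3, extinction=0.1,
                               fossilization=0.1, origin_age=12.0)
        tree, _ = simulate_fbd_tree(cfg, seed=9)
        recs = assign_age_windows(tree, window_width=1.5, seed=1)
        by_name = {r.name: r for r in recs}
        for tip in tree.tips:
            rec = by_name[tip.name]
            if tip.age == 0:
                assert rec.extant and rec.age_window == (0.0, 0.0)
            else:
                lo, hi = rec.age_window
                assert lo <= tip.age <= hi
                assert hi - lo == pytest.approx(1.5)

    def test_zero_width_equals_true_age(self):
        cfg = SimulationConfig(speciation=0.3, extinction=0.1,
                               fossilization=0.1, origin_age=12.0)
        tree, _ = simulate_fbd_tree(cfg, seed=9)
        recs = assign_age_windows(tree, window_width=0.0, seed=1)
        for tip in tree.tips:
            rec = next(r for r in recs if r.name == tip.name)
            if tip.age > 0:
                assert rec.age_window == (tip.age, tip.age)

    def test_uniform_position_across_replicates(self):
        t = TimeTree.from_newick("((A:0,F:5):5,B:10);",
                                 tip_ages={"A": 0.0, "B": 0.0, "F": 5.0})
        pos = []
        for seed in range(2000):
            rec = next(r for r in assign_age_windows(t, 1.5, seed=seed)
                       if r.name == "F")
            lo, hi = rec.age_window
            pos.append((5.0 - lo) / (hi - lo))
        # true age uniformly positioned in the window
        assert abs(np.mean(pos) - 0.5) < 0.02
        assert abs(np.var(pos) - 1 / 12) < 0.01


class TestBiogeographySim:
    def test_zero_dispersal_inherits_root_area(self):
        t = TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        areas, nodes = simulate_biogeography(t, dispersal_rate=0.0, seed=2)
        assert len(set(areas.values())) == 1

    def test_long_branch_uniform_areas(self):
        t = TimeTree.from_newick("((A:900,B:900):50,(C:920,D:920):30);")
        counts = np.zeros(6)
        for seed in range(300):
            areas, _ = simulate_biogeography(t, dispersal_rate=1.0,
                                             seed=seed)
            from tipdating.characters import AREAS
            for a in areas.values():
                counts[AREAS.index(a)] += 1
        freqs = counts / counts.sum()
        assert np.allclose(freqs, 1 / 6, atol=0.05)

    def test_root_area_recovery_at_low_rate(self):
        # reconstruction recovers the true root area in most low-rate
        # replicates
        from tipdating.asr import asr_biogeography
        t = TimeTree.from_newick(
            "(((A:2,B:2):2,(C:3,D:3):1):2,(E:4,F:4):2);")
        hits = 0
        n = 40
        for seed in range(n):
            areas, node_truth = simulate_biogeography(
                t, dispersal_rate=0.05, seed=seed)
            probs = asr_biogeography(t, areas, rate=0.05)
            root_clade = frozenset("ABCDEF")
            from tipdating.characters import AREAS
            best = AREAS[int(np.argmax(probs[root_clade]))]
            hits += best == node_truth[root_clade]
        assert hits / n >= 0.8


class TestMeshes:
    def test_zero_noise_zero_deformation_congruent(self):
        from tipdating.morphometrics import pairwise_align, \
            spread_pseudolandmarks
        meshes, labels = generate_tooth_meshes(1, 3, deformation=0.0,
                                               noise_sd=0.0, seed=3)
        lms = [spread_pseudolandmarks(m, 60, seed=0) for m in meshes]
        al = pairwise_align(lms[0], lms[1])
        assert al.distance < 1e-6

    def test_mirrored_specimens_need_reflections(self):
        from tipdating.morphometrics import pairwise_align, \
            spread_pseudolandmarks
        meshes, _ = generate_tooth_meshes(1, 2, deformation=0.0,
                                          noise_sd=0.0, seed=4,
                                          mirror_fraction=0.0)
        import trimesh
        v = meshes[1].vertices @ np.diag([1.0, 1.0, -1.0])
        mirrored = trimesh.Trimesh(vertices=v, faces=meshes[1].faces,
                                   process=False)
        a = spread_pseudolandmarks(meshes[0], 60, seed=0)
        b = spread_pseudolandmarks(mirrored, 60, seed=0)
        with_refl = pairwise_align(a, b, allow_reflections=True)
        without = pairwise_align(a, b, allow_reflections=False)
        assert with_refl.distance < 1e-6
        assert without.distance > 10 * max(with_refl.distance, 1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(SimulationError):
            generate_tooth_meshes(2, 2, deformation=-1, noise_sd=0.0)


class TestReproducibility:
    def test_bitwise_seed_reproducibility(self):
        cfg = SimulationConfig(seed=17, n_morph=15, n_sites=60,
                               origin_age=10.0, speciation=0.4,
                               fossilization=0.05)
        d1, t1, truth1 = simulate_dataset(cfg)
        d2, t2, truth2 = simulate_dataset(cfg)
        assert t1.to_newick() == t2.to_newick()
        assert d1.morph == d2.morph
        assert np.array_equal(d1.mol.sites, d2.mol.sites)
        assert truth1["root_age"] == truth2["root_age"]
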