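"""Phantom generator: geometry oracles, noise model, and determinism."""

import numpy as np
import pytest

from perfudim.phantom import (
    PhantomConfig,
    apply_occlusion,
    generate_cohort,
    generate_vascular_tree,
    plant_substrate,
    raw_scores,
    render_scan_pair,
    simulate_scores,
)


def cylinder_oracle(p0, p1, radius, shape):
    """Brute-force point-in-cylinder scan over every voxel centre."""
    count = 0
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    len2 = d @ d
    for idx in np.ndindex(*shape):
        pt = np.asarray(idx, float)
        t = np.clip((pt - p0) @ d / len2, 0, 1) if len2 > 0 else 0.0
        if np.linalg.norm(pt - (p0 + t * d)) <= radius:
            count += 1
    return count


class TestTreeGeneration:
    def test_single_branch_matches_cylinder_oracle(self):
        cfg = PhantomConfig(grid_shape=(20, 20, 20), n_branches=1, rng_seed=3)
        tree, field = generate_vascular_tree(cfg)
        assert len(tree.edges) == 1
        p, c = tree.edges[0]
        expected = cylinder_oracle(
            tree.nodes[p], tree.nodes[c], tree.radii[0], cfg.grid_shape
        )
        assert int(field.sum()) == expected

    def test_same_seed_reproduces_tree_exactly(self):
        cfg = PhantomConfig(grid_shape=(24, 24, 24), n_branches=9, rng_seed=5)
        t1, f1 = generate_vascular_tree(cfg)
        t2, f2 = generate_vascular_tree(cfg)
        np.testing.assert_array_equal(t1.nodes, t2.nodes)
        assert t1.edges == t2.edges
        np.testing.assert_array_equal(f1, f2)

    def test_radii_taper_and_tree_is_acyclic(self):
        cfg = PhantomConfig(grid_shape=(32, 32, 32), n_branches=15, rng_seed=7)
        tree, _ = generate_vascular_tree(cfg)
        parent_of = {c: (p, i) for i, (p, c) in enumerate(tree.edges)}
        for i, (p, c) in enumerate(tree.edges):
            if p in parent_of:  # non-root edge: compare with parent edge radius
                assert tree.radii[i] <= tree.radii[parent_of[p][1]] + 1e-12
        # single root, connected, acyclic: n_edges = n_nodes - 1
        assert len(tree.edges) == len(tree.nodes) - 1

    def test_fifteen_branches_reach_four_generations(self):
        cfg = PhantomConfig(grid_shape=(32, 32, 32), n_branches=15, rng_seed=1)
        tree, _ = generate_vascular_tree(cfg)
        depth = {tree.root: 0}
        for p, c in tree.edges:  # edges are in BFS order
            depth[c] = depth[p] + 1
        assert max(depth.values()) >= 4

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(grid_shape=(8, 8, 8))


class TestRendering:
    def test_noiseless_difference_is_exactly_contrast(self):
        cfg = PhantomConfig(grid_shape=(20, 20, 20), n_branches=5, noise_sd=0.0,
                            contrast_level=0.7, rng_seed=2)
        tree, field = generate_vascular_tree(cfg)
        pair = render_scan_pair(tree, cfg)
        diff = pair.cta - pair.ct
        np.testing.assert_allclose(diff[field], 0.7)
        np.testing.assert_allclose(diff[~field], 0.0)

    def test_noisy_contrast_mean_within_monte_carlo_bound(self):
        cfg = PhantomConfig(grid_shape=(28, 28, 28), n_branches=9, noise_sd=0.05,
                            contrast_level=1.0, rng_seed=8)
        tree, field = generate_vascular_tree(cfg)
        pair = render_scan_pair(tree, cfg)
        diff = (pair.cta - pair.ct)[field]
        assert abs(diff.mean() - 1.0) < 3 * 0.05 / np.sqrt(field.sum())

    def test_occluded_vessels_carry_no_contrast(self):
        cfg = PhantomConfig(grid_shape=(24, 24, 24), n_branches=7, noise_sd=0.0,
                            rng_seed=4)
        tree, _ = generate_vascular_tree(cfg)
        occluded, _ = apply_occlusion(tree, len(tree.edges) - 1)
        pair = render_scan_pair(tree, cfg, occluded_edges=occluded)
        occl_field = np.zeros(cfg.grid_shape, bool)
        for eid in occluded:
            v = tree.edge_voxels[eid]
            occl_field[v[:, 0], v[:, 1], v[:, 2]] = True
        open_field = tree.vessel_field(exclude_edges=occluded)
        diff = pair.cta - pair.ct
        assert np.all(diff[occl_field & ~open_field] == 0.0)


class TestOcclusion:
    def test_leaf_occlusion_territory_is_its_own_tube_dilated(self):
        from scipy.ndimage import binary_dilation

        cfg = PhantomConfig(grid_shape=(24, 24, 24), n_branches=7, rng_seed=6)
        tree, _ = generate_vascular_tree(cfg)
        leaves = [
            i for i in range(len(tree.edges)) if not tree.children_of_edge(i)
        ]
        eid = leaves[0]
        occluded, territory = apply_occlusion(tree, eid)
        assert occluded == {eid}
        tube = np.zeros(cfg.grid_shape, bool)
        v = tree.edge_voxels[eid]
        tube[v[:, 0], v[:, 1], v[:, 2]] = True
        np.testing.assert_array_equal(territory, binary_dilation(tube, iterations=2))

    def test_root_occlusion_dominates_every_other_territory(self):
        cfg = PhantomConfig(grid_shape=(24, 24, 24), n_branches=7, rng_seed=6)
        tree, _ = generate_vascular_tree(cfg)
        _, t_root = apply_occlusion(tree, 0)
        for eid in range(1, len(tree.edges)):
            _, t = apply_occlusion(tree, eid)
            assert np.all(t_root[t])  # subtree monotonicity

    def test_territory_count_matches_subtree_flood_oracle(self):
        cfg = PhantomConfig(grid_shape=(24, 24, 24), n_branches=9, rng_seed=12)
        tree, _ = generate_vascular_tree(cfg)
        eid = 1
        occluded, territory = apply_occlusion(tree, eid)
        # independent traversal: repeatedly expand children until fixpoint
        reach = {eid}
        changed = True
        while changed:
            changed = False
            for i, (p, c) in enumerate(tree.edges):
                for j in reach.copy():
                    if p == tree.edges[j][1] and i not in reach:
                        reach.add(i)
                        changed = True
        assert occluded == reach


class TestSubstrate:
    def test_radius_zero_ball_is_single_voxel(self):
        sub = plant_substrate((10, 10, 10), [((4, 5, 6), 0.0, 2.5)])
        assert np.count_nonzero(sub) == 1
        assert sub[4, 5, 6] == 2.5

    def test_empty_region_list_gives_zero_map(self):
        assert not plant_substrate((8, 8, 8), []).any()

    def test_two_disjoint_balls_match_distance_oracle(self):
        regions = [((3.0, 3.0, 3.0), 2.0, 1.0), ((12.0, 12.0, 12.0), 2.5, 2.0)]
        sub = plant_substrate((16, 16, 16), regions)
        count = 0
        for idx in np.ndindex(16, 16, 16):
            pt = np.asarray(idx, float)
            for c, r, _ in regions:
                if np.linalg.norm(pt - np.asarray(c)) <= r:
                    count += 1
                    break
        assert np.count_nonzero(sub) == count

    def test_overlapping_balls_sum(self):
        sub = plant_substrate((10, 10, 10), [((5, 5, 5), 1.5, 1.0),
                                             ((5, 5, 5), 1.5, 2.0)])
        assert sub[5, 5, 5] == 3.0

    def test_out_of_grid_centre_rejected(self):
        with pytest.raises(ValueError):
            plant_substrate((8, 8, 8), [((9.0, 0.0, 0.0), 1.0, 1.0)])


class TestScores:
    def test_zero_substrate_scores_all_zero(self):
        cpms = [np.random.default_rng(i).random((6, 6, 6)) for i in range(4)]
        ordinal, raw = simulate_scores(cpms, np.zeros((6, 6, 6)), noise_sd=0.0)
        assert list(ordinal) == [0, 0, 0, 0]
        assert np.all(raw == 0)

    def test_doubling_cpm_in_support_doubles_raw_score(self):
        sub = plant_substrate((8, 8, 8), [((4, 4, 4), 2.0, 1.0)])
        cpm1 = np.random.default_rng(3).random((8, 8, 8)) + 1.0
        cpm2 = cpm1.copy()
        cpm2[sub > 0] *= 2.0
        raw = raw_scores([cpm1, cpm2], sub)
        assert raw[1] == pytest.approx(2 * raw[0], rel=1e-12)

    def test_raw_scores_match_explicit_voxel_loop(self):
        from perfudim.reference import dot_product_loop

        rng = np.random.default_rng(7)
        sub = rng.random((6, 6, 6))
        cpms = [rng.random((6, 6, 6)) for _ in range(3)]
        raw = raw_scores(cpms, sub)
        for r, c in zip(raw, cpms):
            assert r == pytest.approx(dot_product_loop(sub, c), rel=1e-13)

    def test_quantile_binning_spreads_levels(self):
        rng = np.random.default_rng(8)
        cpms = [rng.random((5, 5, 5)) for _ in range(25)]
        sub = np.ones((5, 5, 5))
        ordinal, _ = simulate_scores(cpms, sub, levels=5)
        assert set(ordinal) == {0, 1, 2, 3, 4}

    def test_constant_raw_scores_collapse_to_level_zero(self):
        cpms = [np.ones((4, 4, 4))] * 5
        ordinal, _ = simulate_scores(cpms, np.ones((4, 4, 4)))
        assert list(ordinal) == [0] * 5


class TestCohort:
    def test_singleton_cohort_invariants(self):
        cfg = PhantomConfig(grid_shape=(16, 16, 16), n_branches=5, rng_seed=3)
        patients, substrate = generate_cohort(1, cfg, rng_seed=3)
        assert len(patients) == 1
        p = patients[0]
        assert p.scan_pair.ct.shape == (16, 16, 16)
        assert p.territory_mask.shape == p.true_substrate.shape == p.cpm.shape
        assert set(p.scores) == {"deficit"}

    def test_same_seed_gives_identical_cohorts(self):
        cfg = PhantomConfig(grid_shape=(16, 16, 16), n_branches=5, rng_seed=4)
        a, sub_a = generate_cohort(2, cfg, rng_seed=4)
        b, sub_b = generate_cohort(2, cfg, rng_seed=4)
        np.testing.assert_array_equal(sub_a, sub_b)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.scan_pair.cta, pb.scan_pair.cta)
            np.testing.assert_array_equal(pa.cpm, pb.cpm)
            assert pa.scores == pb.scores
            assert pa.raw_score == pb.raw_score

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, PhantomConfig(grid_shape=(16, 16, 16)))

    def test_raw_scores_track_substrate_masked_mean_cpm(self):
        """With a constant-weight ball substrate and no score noise, the raw
        deficit is proportional to the substrate-masked mean CPM, so their
        rank correlation across the cohort is essentially perfect."""
        from scipy.stats import spearmanr

        cfg = PhantomConfig(grid_shape=(32, 32, 32), n_branches=15,
                            noise_sd=0.02, rng_seed=21)
        patients, substrate = generate_cohort(8, cfg, rng_seed=21,
                                              score_noise_sd=0.0)
        mask = substrate > 0
        raw = [p.raw_score for p in patients]
        masked_mean = [p.cpm[mask].mean() for p in patients]
        rho = spearmanr(raw, masked_mean).statistic
        assert rho > 0.9
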