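import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import disc_mask
from lipograin import (
    AggregateCensus,
    InstanceSet,
    LabelCount,
    SceneParams,
    aggregate_census,
    attach_densities,
    chi_square_census,
    compare_size_distributions,
    labelling_fraction,
    positive_fraction_by_bin,
    redistribution_percent,
    saturation_curve,
    simulate_micrograph,
)


class TestAttachDensities:
    shape = (120, 120)

    def test_overlapping_blob_attaches(self):
        particles = InstanceSet([disc_mask(self.shape, 40, 40, 15)])
        blobs = InstanceSet([disc_mask(self.shape, 40, 57, 6)])
        counts, unbound = attach_densities(particles, blobs, max_gap_px=2)
        assert counts[0].n_densities == 1
        assert unbound == []

    def test_distant_blob_unbound(self):
        particles = InstanceSet([disc_mask(self.shape, 30, 30, 10)])
        blobs = InstanceSet([disc_mask(self.shape, 90, 90, 5)])
        counts, unbound = attach_densities(particles, blobs, max_gap_px=2)
        assert counts[0].n_densities == 0
        assert unbound == [0]

    def test_blob_goes_to_nearest_particle(self):
        particles = InstanceSet(
            [disc_mask(self.shape, 40, 30, 10), disc_mask(self.shape, 40, 80, 10)]
        )
        blobs = InstanceSet([disc_mask(self.shape, 40, 42, 4)])  # 2 px from first
        counts, _ = attach_densities(particles, blobs, max_gap_px=3)
        assert counts[0].n_densities == 1
        assert counts[1].n_densities == 0

    def test_simulated_scene_counts_match_truth(self):
        p = SceneParams(
            n_particles=60, image_shape=(1200, 1200), seed=21,
            labelled_fraction=0.5, blobs_per_labelled=1.5, aggregate_fraction=0.0,
        )
        _, truth = simulate_micrograph(p)
        counts, unbound = attach_densities(truth.instances, truth.blobs, max_gap_px=2)
        assert unbound == []
        recovered = np.array([c.n_densities for c in counts])
        assert np.array_equal(recovered, truth.table.n_blobs.to_numpy())


class TestLabellingFraction:
    def test_all_and_none(self):
        all_pos = [LabelCount(i, 2) for i in range(7)]
        none = [LabelCount(i, 0) for i in range(7)]
        assert labelling_fraction(all_pos) == 100.0
        assert labelling_fraction(none) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            labelling_fraction([])


class TestSaturationCurve:
    def test_plateau_detected_at_top_concentrations(self):
        res = saturation_curve([1, 2, 4, 8, 16], [10, 30, 36, 37, 36.5])
        assert res["plateau_percent"] == pytest.approx(np.mean([36, 37, 36.5]))
        assert 36.0 <= res["plateau_percent"] <= 37.0

    def test_constant_curve_is_its_own_plateau(self):
        res = saturation_curve([1, 2, 3, 4], [25.0] * 4)
        assert res["plateau_percent"] == pytest.approx(25.0)
        assert res["spearman_rho"] == 0.0

    def test_unstabilized_curve_flags_no_plateau(self):
        res = saturation_curve([1, 2, 3, 4], [10, 25, 45, 70])
        assert res["plateau_percent"] is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            saturation_curve([1, 2], [10, 20])


class TestPositiveFractionByBin:
    def test_all_positive_every_bin_100(self):
        out = positive_fraction_by_bin([20.5, 22.1, 25.0], [True, True, True])
        assert (out.percent_positive == 100.0).all()

    def test_none_positive_zero_everywhere(self):
        out = positive_fraction_by_bin([20.5, 22.1], [False, False])
        assert (out.percent_positive == 0.0).all()

    def test_per_bin_counts(self):
        out = positive_fraction_by_bin([20.1, 21.9, 22.5], [True, False, True])
        row20 = out[out.bin_lower_nm == 20.0].iloc[0]
        assert row20.n == 2 and row20.percent_positive == 50.0


def _census_oracle(instances, gap):
    """Brute-force union-find over exact pairwise Chebyshev pixel distances."""
    n = len(instances)
    coords = [np.argwhere(instances.full_mask(i)) for i in range(n)]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        d = np.abs(coords[i][:, None, :] - coords[j][None, :, :]).max(axis=2).min()
        if d <= gap:
            parent[find(j)] = find(i)
    sizes = {}
    for i in range(n):
        sizes[find(i)] = sizes.get(find(i), 0) + 1
    return sorted(sizes.values())


class TestAggregateCensus:
    def test_isolated_particles_all_singletons(self):
        shape = (200, 200)
        masks = [disc_mask(shape, 30 + 40 * k, 30 + 40 * k, 8) for k in range(5)]
        c = aggregate_census(InstanceSet(masks, shape=shape))
        assert c.counts == {1: 5, 2: 0, 3: 0, "4+": 0}

    def test_chain_of_six_is_one_large_event(self):
        shape = (100, 400)
        masks = [disc_mask(shape, 50, 30 + 16 * k, 8) for k in range(6)]
        c = aggregate_census(InstanceSet(masks, shape=shape))
        assert c.counts == {1: 0, 2: 0, 3: 0, "4+": 1}
        assert c.component_sizes == [6]

    def test_touch_gap_distance_semantics(self):
        # Chebyshev distance: 0 = shared pixel, 1 = 8-adjacent contact,
        # 2 = one background pixel between the masks.
        shape = (60, 120)
        a = disc_mask(shape, 30, 30, 10)  # rightmost col 40
        b = disc_mask(shape, 30, 52, 10)  # leftmost col 42: one empty col
        inst = InstanceSet([a, b], shape=shape)
        assert aggregate_census(inst, touch_gap_px=1).counts[1] == 2
        assert aggregate_census(inst, touch_gap_px=2).counts[2] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_union_find_oracle_on_random_scenes(self, seed):
        rng = np.random.default_rng(seed)
        shape = (160, 160)
        masks = []
        for _ in range(10):
            r = int(rng.integers(3, 7))
            cy = int(rng.integers(10, 150))
            cx = int(rng.integers(10, 150))
            masks.append(disc_mask(shape, cy, cx, r))
        inst = InstanceSet(masks, shape=shape)
        ours = aggregate_census(inst, touch_gap_px=1)
        oracle = AggregateCensus.from_sizes(_census_oracle(inst, 1))
        assert ours.counts == oracle.counts

    def test_permutation_invariance(self, rng):
        shape = (160, 160)
        masks = [disc_mask(shape, int(rng.integers(10, 150)), int(rng.integers(10, 150)), 5)
                 for _ in range(8)]
        inst = InstanceSet(masks, shape=shape)
        perm = rng.permutation(len(masks))
        inst_p = InstanceSet([masks[i] for i in perm], shape=shape)
        assert aggregate_census(inst).counts == aggregate_census(inst_p).counts


class TestChiSquareCensus:
    def test_identical_censuses_give_zero(self):
        a = AggregateCensus({1: 30, 2: 10, 3: 5, "4+": 2})
        chi2, df, p = chi_square_census(a, a)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 3

    def test_df_three_with_all_categories_occupied(self):
        a = AggregateCensus({1: 30, 2: 10, 3: 5, "4+": 2})
        b = AggregateCensus({1: 3, 2: 4, 3: 15, "4+": 40})
        _, df, _ = chi_square_census(a, b)
        assert df == 3

    def test_symmetry(self):
        a = AggregateCensus({1: 30, 2: 10, 3: 5, "4+": 2})
        b = AggregateCensus({1: 3, 2: 4, 3: 15, "4+": 40})
        assert chi_square_census(a, b)[0] == pytest.approx(chi_square_census(b, a)[0])

    def test_zero_expectation_category_pooled(self):
        a = AggregateCensus({1: 30, 2: 10, 3: 0, "4+": 0})
        b = AggregateCensus({1: 20, 2: 15, 3: 0, "4+": 0})
        chi2, df, p = chi_square_census(a, b)
        assert df == 1  # both empty tail categories pooled away

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = AggregateCensus(dict(zip([1, 2, 3, "4+"], rng.integers(1, 50, 4).tolist())))
        b = AggregateCensus(dict(zip([1, 2, 3, "4+"], rng.integers(1, 50, 4).tolist())))
        chi2, df, _ = chi_square_census(a, b)
        obs = np.array([[a.counts[k] for k in (1, 2, 3, "4+")],
                        [b.counts[k] for k in (1, 2, 3, "4+")]], dtype=float)
        total = obs.sum()
        expected_stat = 0.0
        for r in range(2):
            for c in range(4):
                e = obs[r].sum() * obs[:, c].sum() / total
                expected_stat += (obs[r, c] - e) ** 2 / e
        assert chi2 == pytest.approx(expected_stat, abs=1e-9)
        assert df == 3


class TestRedistribution:
    def test_identical_censuses_zero(self):
        a = AggregateCensus({1: 10, 2: 5, 3: 2, "4+": 1}, component_sizes=None)
        assert redistribution_percent(a, a) == pytest.approx(0.0)

    def test_total_redistribution_is_100(self):
        before = AggregateCensus({1: 20, 2: 0, 3: 0, "4+": 0})
        after = AggregateCensus({1: 0, 2: 0, 3: 0, "4+": 4}, component_sizes=[5, 5, 5, 5])
        assert redistribution_percent(before, after) == pytest.approx(100.0)

    def test_hand_computed_case(self):
        # before: 8 singles + 1 pair -> 10 particles, all in small categories
        before = AggregateCensus({1: 8, 2: 1, 3: 0, "4+": 0})
        # after: 2 singles + 2 four-particle aggregates -> share 2/10
        after = AggregateCensus({1: 2, 2: 0, 3: 0, "4+": 2}, component_sizes=[1, 1, 4, 4])
        assert redistribution_percent(before, after) == pytest.approx(100.0 * (1.0 - 0.2))

    def test_unrecorded_large_events_weighted_as_four(self):
        before = AggregateCensus({1: 4, 2: 0, 3: 0, "4+": 0})
        after = AggregateCensus({1: 0, 2: 0, 3: 0, "4+": 1})  # counts 4 particles
        assert redistribution_percent(before, after) == pytest.approx(100.0)


class TestCompareSizeDistributions:
    def test_identical_groups_h_zero_ks_zero(self):
        g = [18.0, 20.0, 22.0, 24.0, 26.0]
        rep = compare_size_distributions([g, list(g), list(g)])
        assert rep["kruskal_H"] == pytest.approx(0.0, abs=1e-9)
        assert rep["kruskal_df"] == 2
        assert rep["pairwise_ks"][(0, 1)][0] == 0.0

    def test_disjoint_supports_ks_one(self):
        rep = compare_size_distributions([[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]])
        assert rep["pairwise_ks"][(0, 1)][0] == 1.0

    def test_h_matches_rank_formula_with_ties(self, rng):
        groups = [rng.integers(0, 8, 6).astype(float).tolist() for _ in range(3)]
        rep = compare_size_distributions(groups)
        # independent tie-corrected rank computation
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = pooled.size
        h = 0.0
        start = 0
        for g in groups:
            r = ranks[start : start + len(g)]
            h += r.sum() ** 2 / len(g)
            start += len(g)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        _, tie_counts = np.unique(pooled, return_counts=True)
        correction = 1 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
        assert rep["kruskal_H"] == pytest.approx(h / correction, abs=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            compare_size_distributions([[1.0]])
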