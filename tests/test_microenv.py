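import math

import numpy as np
import pandas as pd
import pytest

from decimap.microenv import (
    NeighborhoodSpec,
    adjacency_matrix,
    aggregate_sample,
    corrected_enrichment,
    enrichment_matrix,
    expected_pct,
    neighbors_within,
    observed_pct,
    permutation_null,
    row_zscore,
)

from conftest import make_roi

SPEC = NeighborhoodSpec(radius_um=10.0, n_permutations=200, seed=0)


def brute_force_pairs(xy, radius):
    """O(n²) distance-matrix neighbour pairs (i < j), the oracle."""
    xy = np.asarray(xy, float)
    out = set()
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            if math.dist(xy[i], xy[j]) <= radius:
                out.add((i, j))
    return out


class TestNeighbors:
    def test_distance_exactly_radius_is_neighbor(self):
        roi = make_roi([(0, 0), (10, 0)], ["A", "B"])
        assert len(neighbors_within(roi, SPEC)) == 1

    def test_distance_just_over_radius_is_not(self):
        roi = make_roi([(0, 0), (10.01, 0)], ["A", "B"])
        assert len(neighbors_within(roi, SPEC)) == 0

    def test_matches_brute_force_on_random_roi(self):
        rng = np.random.default_rng(42)
        xy = rng.uniform(0, 300, size=(500, 2))
        roi = make_roi(xy, ["A"] * 500, width=300, height=300)
        found = {tuple(p) for p in neighbors_within(roi, SPEC)}
        assert found == brute_force_pairs(xy, SPEC.radius_um)

    def test_adjacency_is_symmetric_without_diagonal(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 100, size=(80, 2))
        roi = make_roi(xy, ["A"] * 80, width=100, height=100)
        adj = adjacency_matrix(roi, SPEC).toarray()
        assert (adj == adj.T).all()
        assert np.diag(adj).sum() == 0


#: 4-cell hand-computed configuration: A at origin, one B in radius,
#: one B far, one C far.
HAND_XY = [(0, 0), (5, 0), (30, 0), (0, 30)]
HAND_LABELS = ["A", "B", "B", "C"]


class TestObservedExpectedCorrected:
    def test_single_partner_in_radius_gives_100(self):
        roi = make_roi([(0, 0), (5, 0)], ["A", "B"])
        assert observed_pct(roi, "A", "B", SPEC) == 100.0

    def test_partner_out_of_radius_gives_0(self):
        roi = make_roi([(0, 0), (15, 0)], ["A", "B"])
        assert observed_pct(roi, "A", "B", SPEC) == 0.0

    def test_hand_configuration(self):
        roi = make_roi(HAND_XY, HAND_LABELS)
        assert observed_pct(roi, "A", "B", SPEC) == 100.0
        assert expected_pct(roi, "B") == 50.0
        res = corrected_enrichment(roi, "A", "B", SPEC)
        assert res.corrected == 50.0
        assert res.corrected == res.observed_pct - res.expected_pct

    def test_no_source_cells_is_undefined_not_zero(self):
        roi = make_roi(HAND_XY, HAND_LABELS)
        with pytest.raises(KeyError, match="Z"):
            observed_pct(roi, "Z", "B", SPEC, universe={"A", "B", "C"})
        # a known phenotype with zero members in this ROI is undefined, not 0
        roi2 = make_roi([(0, 0), (5, 0)], ["B", "B"])
        assert math.isnan(observed_pct(roi2, "A", "B", SPEC, universe={"A", "B"}))
        res = aggregate_sample([roi2], "A", "B", SPEC, with_permutation=False)
        assert res.n_source == 0
        assert math.isnan(res.observed_pct)
        assert not res.defined

    def test_self_pair_excludes_focal_cell(self):
        # all cells B, mutually within radius: observed(B->B) = 100,
        # expected(B) = 100, corrected = 0
        roi = make_roi([(0, 0), (5, 0), (0, 5)], ["B", "B", "B"])
        assert observed_pct(roi, "B", "B", SPEC) == 100.0
        assert expected_pct(roi, "B") == 100.0
        assert corrected_enrichment(roi, "B", "B", SPEC).corrected == 0.0
        # an isolated B has no B neighbour
        roi2 = make_roi([(0, 0)], ["B"])
        assert observed_pct(roi2, "B", "B", SPEC) == 0.0

    def test_absent_target_gives_negative_frequency_correction(self):
        labels = ["A"] * 2 + ["B"] * 2 + ["C"] * 6
        xy = [(i * 50, 0) for i in range(10)]  # nothing within 10 um
        roi = make_roi(xy, labels)
        res = corrected_enrichment(roi, "A", "B", SPEC)
        assert res.observed_pct == 0.0
        assert res.corrected == -20.0

    def test_expected_pct_sums_to_100_over_universe(self):
        rng = np.random.default_rng(9)
        labels = rng.choice(["A", "B", "C", "D"], size=200)
        roi = make_roi(rng.uniform(0, 500, (200, 2)), labels, width=500, height=500)
        total = sum(expected_pct(roi, ph) for ph in "ABCD")
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_observed_monotone_in_radius(self):
        rng = np.random.default_rng(17)
        labels = rng.choice(["A", "B"], size=150)
        roi = make_roi(rng.uniform(0, 300, (150, 2)), labels, width=300, height=300)
        values = [
            observed_pct(roi, "A", "B", NeighborhoodSpec(radius_um=r, n_permutations=100))
            for r in (5, 10, 20, 40, 80)
        ]
        assert values == sorted(values)

    def test_asymmetry_preserved(self):
        # 1 A surrounded by 3 B: obs(A->B)=100, obs(B->A)=100; but with
        # an extra far B, obs(B->A) drops while obs(A->B) stays.
        roi = make_roi([(0, 0), (5, 0), (0, 5), (200, 200)], ["A", "B", "B", "B"])
        assert observed_pct(roi, "A", "B", SPEC) == 100.0
        assert observed_pct(roi, "B", "A", SPEC) == pytest.approx(200.0 / 3)


class TestPermutationNull:
    def test_single_phenotype_roi_has_undefined_z(self):
        roi = make_roi([(0, 0), (5, 0), (0, 5)], ["B", "B", "B"])
        res = permutation_null(roi, "B", "B", SPEC)
        assert not res.z_defined
        assert not res.significant
        assert math.isnan(res.perm_z)

    def test_same_seed_reproduces_z_exactly(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["A", "B", "C"], size=120)
        roi = make_roi(rng.uniform(0, 200, (120, 2)), labels, width=200, height=200)
        z1 = permutation_null(roi, "A", "B", SPEC).perm_z
        z2 = permutation_null(roi, "A", "B", SPEC).perm_z
        assert z1 == z2
        z3 = permutation_null(roi, "A", "B", NeighborhoodSpec(n_permutations=200, seed=99)).perm_z
        assert z1 != z3

    def test_significance_consistent_with_cutoff(self):
        rng = np.random.default_rng(8)
        # strong planted signal: B cells placed on top of A cells
        a_xy = rng.uniform(0, 400, (40, 2))
        b_xy = a_xy + rng.normal(0, 2, (40, 2))
        c_xy = rng.uniform(0, 400, (120, 2))
        xy = np.clip(np.vstack([a_xy, b_xy, c_xy]), 0, 400)
        labels = ["A"] * 40 + ["B"] * 40 + ["C"] * 120
        roi = make_roi(xy, labels, width=400, height=400)
        res = permutation_null(roi, "A", "B", SPEC)
        assert res.z_defined
        assert res.significant == (abs(res.perm_z) > SPEC.z_cutoff)
        assert res.perm_z > SPEC.z_cutoff


class TestAggregateSample:
    def test_pooled_observed_is_source_weighted(self):
        # ROI1: 10 A all with a B partner; ROI2: 30 A with none
        xy1 = [(i * 30, 0) for i in range(10)] + [(i * 30, 5) for i in range(10)]
        roi1 = make_roi(xy1, ["A"] * 10 + ["B"] * 10, roi_id="R1")
        xy2 = [(i * 30, 0) for i in range(30)] + [(i * 30 + 15, 500) for i in range(5)]
        roi2 = make_roi(xy2, ["A"] * 30 + ["B"] * 5, roi_id="R2")
        res = aggregate_sample([roi1, roi2], "A", "B", SPEC, with_permutation=False)
        assert res.observed_pct == pytest.approx(25.0)

    def test_single_roi_equals_roi_level(self):
        rng = np.random.default_rng(12)
        labels = rng.choice(["A", "B", "C"], size=100)
        roi = make_roi(rng.uniform(0, 300, (100, 2)), labels, width=300, height=300)
        sample = aggregate_sample([roi], "A", "B", SPEC, with_permutation=False)
        single = corrected_enrichment(roi, "A", "B", SPEC)
        assert sample.observed_pct == single.observed_pct
        assert sample.expected_pct == single.expected_pct
        assert sample.corrected == single.corrected

    def test_pooling_equals_concatenated_table_with_disjoint_adjacency(self):
        # oracle: shift the second ROI far away and recompute on one table
        rng = np.random.default_rng(21)
        n1, n2 = 80, 120
        xy1 = rng.uniform(0, 300, (n1, 2))
        xy2 = rng.uniform(0, 300, (n2, 2))
        l1 = rng.choice(["A", "B", "C"], size=n1)
        l2 = rng.choice(["A", "B", "C"], size=n2)
        roi1 = make_roi(xy1, l1, roi_id="R1", width=300, height=300)
        roi2 = make_roi(xy2, l2, roi_id="R2", width=300, height=300)
        pooled = aggregate_sample([roi1, roi2], "A", "B", SPEC, with_permutation=False)
        # concatenated: second ROI offset by 10000 um so no cross-ROI pairs
        xy_cat = np.vstack([xy1, xy2 + 10000.0])
        cat = make_roi(xy_cat, list(l1) + list(l2), roi_id="CAT", width=20000, height=20000)
        obs_cat = observed_pct(cat, "A", "B", SPEC)
        exp_cat = expected_pct(cat, "B")
        assert pooled.observed_pct == pytest.approx(obs_cat)
        assert pooled.expected_pct == pytest.approx(exp_cat)

    def test_rois_from_different_samples_rejected(self):
        roi1 = make_roi([(0, 0)], ["A"], roi_id="R1", sample_id="S1")
        roi2 = make_roi([(0, 0)], ["A"], roi_id="R2", sample_id="S2")
        with pytest.raises(ValueError, match="multiple samples"):
            aggregate_sample([roi1, roi2], "A", "A", SPEC)


class TestEnrichmentMatrixAndRowZ:
    def test_row_z_simple(self):
        m = pd.DataFrame([[2.0, 4.0, 6.0]], index=["A->B"], columns=["s1", "s2", "s3"])
        z, flags = row_zscore(m)
        assert list(z.loc["A->B"]) == pytest.approx([-1.0, 0.0, 1.0])
        assert not flags.loc["A->B"]

    def test_constant_row_flagged_and_zeroed(self):
        m = pd.DataFrame([[3.0, 3.0, 3.0]], index=["A->B"], columns=["s1", "s2", "s3"])
        z, flags = row_zscore(m)
        assert list(z.loc["A->B"]) == [0.0, 0.0, 0.0]
        assert bool(flags.loc["A->B"])

    def test_row_z_matches_direct_formula(self):
        rng = np.random.default_rng(31)
        m = pd.DataFrame(rng.normal(size=(3, 5)))
        z, _ = row_zscore(m)
        expected = m.sub(m.mean(axis=1), axis=0).div(m.std(axis=1, ddof=1), axis=0)
        pd.testing.assert_frame_equal(z, expected)

    def test_matrix_shape_and_needs_two_samples(self):
        rng = np.random.default_rng(4)
        rois = {
            s: [
                make_roi(
                    rng.uniform(0, 200, (60, 2)),
                    rng.choice(["A", "B"], size=60),
                    roi_id=f"{s}_R0",
                    sample_id=s,
                    width=200,
                    height=200,
                )
            ]
            for s in ("s1", "s2", "s3")
        }
        matrix, results = enrichment_matrix(rois, ("A", "B"), SPEC)
        assert matrix.shape == (4, 3)
        assert len(results) == 12
        with pytest.raises(ValueError, match=">= 2"):
            enrichment_matrix({"s1": rois["s1"]}, ("A", "B"), SPEC)
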