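"""Valley-cluster extraction, subject assignment, and agreement scoring."""

import numpy as np
import pytest

import torusom as t
from torusom.cluster import connected_valley_components


def flood_fill_oracle(mask):
    """BFS connected components with toroidal 8-connectivity."""
    rows, cols = mask.shape
    labels = np.zeros_like(mask, dtype=int)
    k = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and labels[r0, c0] == 0:
                k += 1
                stack = [(r0, c0)]
                labels[r0, c0] = k
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            if dr == dc == 0:
                                continue
                            rr, cc = (r + dr) % rows, (c + dc) % cols
                            if mask[rr, cc] and labels[rr, cc] == 0:
                                labels[rr, cc] = k
                                stack.append((rr, cc))
    return labels, k


def _ustar(heights):
    heights = np.asarray(heights, dtype=float)
    return t.HeightMatrix(t.GridSpec(*heights.shape), heights, "Ustar")


class TestConnectedComponents:
    def test_agrees_with_flood_fill_on_random_masks(self, rng):
        for _ in range(50):
            mask = rng.random((6, 9)) < rng.uniform(0.2, 0.8)
            labels, k = connected_valley_components(mask)
            ref_labels, ref_k = flood_fill_oracle(mask)
            assert k == ref_k
            # same partition (label values may differ only by renaming)
            for lab in range(1, k + 1):
                members = labels == lab
                assert members.any()
                ref_ids = np.unique(ref_labels[members])
                assert len(ref_ids) == 1 and ref_ids[0] != 0

    def test_wrap_joins_components_across_both_seams(self):
        mask = np.zeros((5, 8), dtype=bool)
        mask[0, 0] = mask[4, 7] = True  # diagonal wrap corner adjacency
        labels, k = connected_valley_components(mask, toroidal=True)
        assert k == 1
        _, k_planar = connected_valley_components(mask, toroidal=False)
        assert k_planar == 2


class TestExtractClusters:
    def test_two_basins_separated_by_wrapped_ridge(self):
        """8x12 landscape: high ridge columns split the torus into two valleys."""
        h = np.zeros((8, 12))
        h[:, 3] = h[:, 4] = 10.0   # ridge band 1
        h[:, 9] = h[:, 10] = 10.0  # ridge band 2 (basins wrap across column 0)
        h[:, :3] -= 1.0            # make basin A slightly deeper
        assignment = t.extract_clusters(_ustar(h), threshold_quantile=0.6)
        assert assignment.n_clusters == 2
        # basin A: columns 11,0,1,2 wrap together; basin B: columns 5..8
        a = assignment.unit_labels[0, 0]
        b = assignment.unit_labels[0, 6]
        assert a != b
        assert (assignment.unit_labels[:, [11, 0, 1, 2]] == a).all()
        assert (assignment.unit_labels[:, 5:9] == b).all()

    def test_ridge_fill_assigns_nearest_valley_with_tie_to_lower_id(self):
        h = np.full((4, 9), 5.0)
        h[:, 1] = 0.0            # valley column -> cluster 1 (first row-major)
        h[:, 6] = 0.0            # valley column -> cluster 2
        assignment = t.extract_clusters(_ustar(h), threshold_quantile=0.2)
        assert assignment.n_clusters == 2
        labels = assignment.unit_labels
        assert labels[0, 1] == 1 and labels[0, 6] == 2
        assert (labels[:, [0, 2, 3]] == 1).all()   # nearer to column 1
        assert (labels[:, [4, 5, 7]] == 2).all()   # nearer to column 6
        # column 8 is wrapped-equidistant (2 units from both): lower id wins
        assert (labels[:, 8] == 1).all()

    def test_constant_heights_single_cluster_with_warning(self):
        with pytest.warns(UserWarning, match="no structure|single cluster"):
            assignment = t.extract_clusters(_ustar(np.full((6, 6), 2.0)))
        assert assignment.n_clusters == 1
        assert (assignment.unit_labels == 1).all()

    def test_every_unit_labeled_and_ids_contiguous(self, rng):
        h = rng.random((10, 15))
        assignment = t.extract_clusters(_ustar(h), threshold_quantile=0.7)
        assert (assignment.unit_labels >= 1).all()
        ids = np.unique(assignment.unit_labels)
        np.testing.assert_array_equal(ids, np.arange(1, assignment.n_clusters + 1))

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError):
            t.extract_clusters(_ustar(np.random.rand(4, 4)), threshold_quantile=1.5)


class TestAssignSubjects:
    def test_subjects_inherit_bmu_cluster(self):
        h = np.zeros((4, 8))
        h[:, 3:5] = 9.0
        assignment = t.extract_clusters(_ustar(h), threshold_quantile=0.6)
        bmus = np.array([[0, 0], [2, 6], [3, 1]])
        out = t.assign_subjects(assignment, bmus)
        assert out.subject_labels.shape == (3,)
        assert out.subject_labels[0] == assignment.unit_labels[0, 0]
        assert out.subject_labels[1] == assignment.unit_labels[2, 6]

    def test_permutation_equivariance(self, rng):
        h = rng.random((6, 9))
        assignment = t.extract_clusters(_ustar(h), threshold_quantile=0.7)
        bmus = np.column_stack([rng.integers(0, 6, 20), rng.integers(0, 9, 20)])
        perm = rng.permutation(20)
        a = t.assign_subjects(assignment, bmus).subject_labels
        b = t.assign_subjects(assignment, bmus[perm]).subject_labels
        np.testing.assert_array_equal(a[perm], b)

    def test_out_of_grid_bmu_rejected(self):
        assignment = t.extract_clusters(_ustar(np.random.rand(4, 4)), 0.5)
        with pytest.raises(IndexError):
            t.assign_subjects(assignment, np.array([[4, 0]]))


class TestEvaluateAgreement:
    def test_ceramide_style_confusion(self):
        # 91 of 102 patients in a pure patient cluster, all controls elsewhere
        rep = t.report_from_confusion(tp=91, fn=11, tn=301, fp=0)
        assert rep.rounded() == {"sensitivity": 89.2, "specificity": 100.0,
                                 "balanced_accuracy": 94.6}

    def test_eicosanoid_style_confusion(self):
        rep = t.report_from_confusion(tp=55, fn=47, tn=301, fp=0)
        assert round(rep.sensitivity) == 54
        assert round(rep.specificity) == 100
        assert round(rep.balanced_accuracy) == 77

    def test_perfect_assignment(self):
        clusters = np.array([1] * 10 + [2] * 20)
        truth = np.array(["patient"] * 10 + ["control"] * 20)
        rep = t.evaluate_agreement(clusters, truth)
        assert (rep.sensitivity, rep.specificity, rep.balanced_accuracy) == (100.0, 100.0, 100.0)

    def test_balanced_accuracy_identity_and_count_conservation(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            clusters = rng.integers(1, 5, n)
            truth = np.where(rng.random(n) < 0.4, "patient", "control")
            if len(np.unique(truth)) < 2:
                continue
            rep = t.evaluate_agreement(clusters, truth)
            assert rep.balanced_accuracy == (rep.sensitivity + rep.specificity) / 2
            assert rep.tp + rep.fn == (truth == "patient").sum()
            assert rep.tn + rep.fp == (truth == "control").sum()

    def test_majority_tie_maps_to_control(self):
        clusters = np.array([1, 1, 2, 2])
        truth = np.array(["patient", "control", "patient", "patient"])
        rep = t.evaluate_agreement(clusters, truth)
        assert rep.cluster_to_class[1] == "control"  # 1-1 tie -> control
        assert rep.cluster_to_class[2] == "patient"

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            t.evaluate_agreement(np.array([1, 1]), np.array(["patient", "patient"]))


class TestUStarClustererEstimator:
    def test_fit_produces_labels_and_matrices(self, trained_small):
        _, pre = trained_small
        cl = t.UStarClusterer(rows=10, cols=16, epochs=10, radius_start=4.0,
                              random_state=3).fit(pre.values)
        assert cl.labels_.shape == (len(pre.subjects),)
        assert cl.u_star_matrix_.kind == "Ustar"
        assert (cl.u_star_matrix_.heights <= cl.u_matrix_.heights + 1e-12).all()
        rep = cl.score_agreement(pre.meta["group"].to_numpy())
        assert rep.tp + rep.fn == (pre.meta["group"] == "patient").sum()
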