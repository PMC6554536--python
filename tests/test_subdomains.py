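"""Strain-percentile partitioning, single-layer reassignment, problem extraction."""

import numpy as np
import pytest

from scleramap.errors import DegenerateSubdomainError, ParameterError
from scleramap.kinematics import DisplacementField
from scleramap.mesh import build_edge_adjacency
from scleramap.subdomains import (
    SubdomainLabeling,
    extract_subdomain_problem,
    find_single_layer_regions,
    partition_by_strain_percentile,
    reassign_single_layer,
)


class TestPartition:
    def test_quartiles_of_distinct_values(self):
        # brute-force oracle: ranks 0..7 into 4 equal bins
        lab = partition_by_strain_percentile(np.arange(1.0, 9.0), K=4)
        assert lab.labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_single_bin(self):
        lab = partition_by_strain_percentile(np.array([0.1, 0.5, 0.9]), K=1)
        assert lab.labels.tolist() == [1, 1, 1]

    def test_equal_counts_within_one(self):
        rng = np.random.default_rng(0)
        e1 = rng.random(1003)
        lab = partition_by_strain_percentile(e1, K=4)
        counts = np.bincount(lab.labels)[1:]
        assert counts.max() - counts.min() <= 1

    def test_ties_go_to_lower_bin(self):
        e1 = np.array([0.0, 0.5, 0.5, 1.0])
        lab = partition_by_strain_percentile(e1, K=2)
        # the two tied elements split by index: earlier index to lower bin
        assert lab.labels.tolist() == [1, 1, 2, 2]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        e1 = rng.random(200)
        perm = rng.permutation(200)
        lab = partition_by_strain_percentile(e1, K=5)
        lab_p = partition_by_strain_percentile(e1[perm], K=5)
        assert np.array_equal(lab_p.labels, lab.labels[perm])

    def test_explicit_edges(self):
        e1 = np.linspace(0, 1, 11)
        lab = partition_by_strain_percentile(e1, K=3, edges=np.array([0.25, 0.75]))
        assert lab.labels.min() == 1 and lab.labels.max() == 3
        assert (lab.labels[e1 < 0.25] == 1).all()

    def test_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            partition_by_strain_percentile(np.ones(10), K=2)
        with pytest.raises(ParameterError):
            partition_by_strain_percentile(np.arange(3.0), K=5)


def _chain_adjacency(labels_len):
    """1D chain of elements: i neighbors i-1 and i+1."""
    return [
        np.array([j for j in (i - 1, i + 1) if 0 <= j < labels_len], dtype=int)
        for i in range(labels_len)
    ]


class TestSingleLayer:
    def test_uniform_labeling_no_strips(self, strip_mesh):
        adjacency = build_edge_adjacency(strip_mesh)
        lab = SubdomainLabeling(np.ones(strip_mesh.n_triangles, int), np.empty(0), 1)
        assert find_single_layer_regions(lab, adjacency) == []

    def test_chain_strip_detected(self):
        labels = np.array([1, 1, 1, 2, 3, 3, 3])
        lab = SubdomainLabeling(labels, np.array([0.3, 0.6]), 3)
        strips = find_single_layer_regions(lab, _chain_adjacency(7))
        assert len(strips) == 1 and strips[0].tolist() == [3]

    def test_block_with_interior_not_flagged(self):
        # 3x3 block of label 2 inside label 1: center element is interior
        m = 25
        labels = np.ones(m, int)
        grid = np.arange(m).reshape(5, 5)
        block = grid[1:4, 1:4].ravel()
        labels[block] = 2
        adjacency = [
            np.array(
                [j for j in (i - 1, i + 1, i - 5, i + 5)
                 if 0 <= j < m and not (i % 5 == 0 and j == i - 1)
                 and not (i % 5 == 4 and j == i + 1)],
                dtype=int,
            )
            for i in range(m)
        ]
        lab = SubdomainLabeling(labels, np.array([0.5]), 2)
        strips = find_single_layer_regions(lab, adjacency)
        assert all(2 not in labels[s] for s in strips)

    def test_reassignment_by_strain_difference(self):
        # strip (element 3) between label-1 and label-3 fields
        labels = np.array([1, 1, 1, 2, 3, 3, 3])
        e1 = np.array([0.46, 0.47, 0.48, 0.50, 0.60, 0.62, 0.64])
        adjacency = _chain_adjacency(7)
        lab = SubdomainLabeling(labels, np.array([0.3, 0.6]), 3)
        strips = find_single_layer_regions(lab, adjacency)
        out = reassign_single_layer(lab, strips, e1, adjacency)
        # adjacent label-1 element has E1 0.48 (diff 0.02) vs label-3 0.60 (diff 0.10)
        assert out.labels[3] == 1
        assert find_single_layer_regions(out, adjacency) == []

    def test_tie_breaks_to_lower_label(self):
        labels = np.array([1, 1, 2, 3, 3])
        e1 = np.array([0.40, 0.45, 0.50, 0.55, 0.60])
        adjacency = _chain_adjacency(5)
        lab = SubdomainLabeling(labels, np.array([0.3, 0.6]), 3)
        strips = find_single_layer_regions(lab, adjacency)
        out = reassign_single_layer(lab, strips, e1, adjacency)
        assert out.labels[2] == 1  # |0.45-0.5| == |0.55-0.5|: lower label wins

    def test_no_strips_is_identity(self):
        labels = np.array([1, 1, 2, 2])
        lab = SubdomainLabeling(labels, np.array([0.5]), 2)
        out = reassign_single_layer(lab, [], np.arange(4.0), _chain_adjacency(4))
        assert np.array_equal(out.labels, labels)

    def test_fixpoint_on_mesh_partition(self, fine_hemisphere):
        from scleramap.kinematics import strain_field

        rng = np.random.default_rng(5)
        u = 0.02 * rng.standard_normal((fine_hemisphere.n_nodes, 3))
        e1 = strain_field(fine_hemisphere, u, smooth_iterations=10)
        adjacency = build_edge_adjacency(fine_hemisphere)
        lab = partition_by_strain_percentile(e1, K=4)
        strips = find_single_layer_regions(lab, adjacency)
        out = reassign_single_layer(lab, strips, e1, adjacency)
        assert find_single_layer_regions(out, adjacency) == []


class TestConnectedComponentSplit:
    def test_disconnected_bin_split_and_connected_kept(self):
        from scleramap.subdomains import split_into_connected_components

        # chain: label 1 appears in two separated runs
        labels = np.array([1, 1, 2, 2, 1, 1])
        lab = SubdomainLabeling(labels, np.array([0.5]), 2)
        out = split_into_connected_components(lab, _chain_adjacency(6))
        assert out.K == 3
        assert out.labels.tolist() == [1, 1, 2, 2, 3, 3]

    def test_already_connected_is_relabeled_identity(self):
        from scleramap.subdomains import split_into_connected_components

        labels = np.array([1, 1, 2, 2])
        lab = SubdomainLabeling(labels, np.array([0.5]), 2)
        out = split_into_connected_components(lab, _chain_adjacency(4))
        assert out.K == 2 and out.labels.tolist() == [1, 1, 2, 2]


class TestExtraction:
    def _field(self, mesh, protocol, scale=0.01):
        rng = np.random.default_rng(0)
        u = np.zeros((4, mesh.n_nodes, 3))
        u[1:] = scale * rng.standard_normal((3, mesh.n_nodes, 3))
        return DisplacementField(protocol.all_pressures, u)

    def test_single_subdomain_boundary_is_global_boundary(self, hemisphere, protocol):
        lab = SubdomainLabeling(np.ones(hemisphere.n_triangles, int), np.empty(0), 1)
        field = self._field(hemisphere, protocol)
        sub = extract_subdomain_problem(
            hemisphere, lab, 1, field, 1.0, np.array([0, 0, 1.0]), 0.2, protocol
        )
        expected = set(hemisphere.rim_nodes) | set(hemisphere.hole_nodes)
        assert set(sub.node_map[sub.boundary_nodes]) == expected

    def test_shared_nodes_in_both_boundaries(self, strip_mesh, protocol):
        labels = np.ones(strip_mesh.n_triangles, int)
        labels[strip_mesh.centroids()[:, 0] > 4.0] = 2
        lab = SubdomainLabeling(labels, np.array([0.5]), 2)
        field = self._field(strip_mesh, protocol)
        subs = [
            extract_subdomain_problem(
                strip_mesh, lab, sid, field, 1.0, np.array([1.0, 0, 0]), 0.2, protocol
            )
            for sid in (1, 2)
        ]
        shared = set(subs[0].node_map[subs[0].boundary_nodes]) & set(
            subs[1].node_map[subs[1].boundary_nodes]
        )
        interface = set(np.intersect1d(
            strip_mesh.triangles[labels == 1], strip_mesh.triangles[labels == 2]
        ).tolist())
        assert interface <= shared

    def test_prescribed_displacements_attached_per_step(self, hemisphere, protocol):
        lab = SubdomainLabeling(np.ones(hemisphere.n_triangles, int), np.empty(0), 1)
        field = self._field(hemisphere, protocol)
        sub = extract_subdomain_problem(
            hemisphere, lab, 1, field, 1.0, np.array([0, 0, 1.0]), 0.2, protocol
        )
        assert sub.prescribed_u.shape == (3, len(sub.boundary_nodes), 3)
        g = sub.node_map[sub.boundary_nodes]
        assert np.allclose(sub.prescribed_u, field.u[1:][:, g, :])

    def test_invalid_id_rejected(self, hemisphere, protocol):
        lab = SubdomainLabeling(np.ones(hemisphere.n_triangles, int), np.empty(0), 1)
        field = self._field(hemisphere, protocol)
        with pytest.raises(ParameterError):
            extract_subdomain_problem(
                hemisphere, lab, 5, field, 1.0, np.array([0, 0, 1.0]), 0.2, protocol
            )

    def test_degenerate_subdomain_rejected(self, strip_mesh, protocol):
        # label 2 = a single triangle: all its nodes touch label 1
        labels = np.ones(strip_mesh.n_triangles, int)
        labels[0] = 2
        lab = SubdomainLabeling(labels, np.array([0.5]), 2)
        field = self._field(strip_mesh, protocol)
        with pytest.raises(DegenerateSubdomainError):
            extract_subdomain_problem(
                strip_mesh, lab, 2, field, 1.0, np.array([1.0, 0, 0]), 0.2, protocol
            )
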