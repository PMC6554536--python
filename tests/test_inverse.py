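"""DOE bounding, residual metrics, PSO determinism, map smoothing, global check."""

import numpy as np
import pytest

from scleramap.errors import ParameterError
from scleramap.forward import PressureProtocol, SolverConfig
from scleramap.inverse import (
    DOEGrid,
    OptimizationResult,
    PSOConfig,
    displacement_sse,
    global_check,
    mean_displacement_error,
    merge_and_smooth_parameters,
    optimize_subdomain,
    run_doe,
)
from scleramap.mesh import build_edge_adjacency
from scleramap.subdomains import SubdomainLabeling, extract_subdomain_problem
from scleramap.synthetic import make_ground_truth, simulate_inflation_experiment

FAST = SolverConfig(sub_increments=1, max_iterations=25, max_line_search=6, max_retries=1)


@pytest.fixture(scope="module")
def small_truth(fine_hemisphere):
    """Homogeneous shell + noiseless synthetic experiment + subdomain problem."""
    protocol = PressureProtocol()
    truth = make_ground_truth(fine_hemisphere, n_regions=1, seed=3)
    field = simulate_inflation_experiment(truth, protocol, noise_sigma=0.0, seed=0)
    labels = np.ones(fine_hemisphere.n_triangles, int)
    labels[fine_hemisphere.centroids()[:, 2] > 7.0] = 2
    lab = SubdomainLabeling(labels, np.array([0.5]), 2)
    sub = extract_subdomain_problem(
        fine_hemisphere, lab, 2, field, truth.thickness, truth.fibers,
        truth.element_param("kappa"), protocol,
    )
    return truth, field, sub


class TestMetrics:
    def test_sse_trivials(self):
        u = np.random.default_rng(0).standard_normal((3, 10, 3))
        assert displacement_sse(u, u, np.arange(10)) == 0.0
        v = u.copy()
        v[1, 4, 0] += 0.02
        assert np.isclose(displacement_sse(v, u, np.arange(10)), 4e-4)
        w = u.copy()
        w[:, 4, 0] += 0.02
        assert np.isclose(displacement_sse(w, u, np.arange(10)), 3 * 4e-4)

    def test_mean_error_arithmetic(self):
        u = np.zeros((1, 2, 3))
        v = u.copy()
        v[0, 0, 0] = 0.01
        m = mean_displacement_error(v, u, np.arange(2))
        assert np.isclose(m["mean_norm_mm"], 0.005)
        assert np.isclose(m["sse_per_node_mm2"], 1e-4 / 2)

    def test_constant_offset(self):
        u = np.zeros((2, 5, 3))
        v = u + np.array([3e-3, 4e-3, 0.0])  # norm 5e-3 everywhere
        m = mean_displacement_error(v, u, np.arange(5))
        assert np.isclose(m["mean_norm_mm"], 5e-3)

    def test_zero_interior_nodes_rejected(self):
        u = np.zeros((1, 3, 3))
        with pytest.raises(ParameterError):
            mean_displacement_error(u, u, np.array([], dtype=int))


class TestDOE:
    def test_grid_validation(self):
        with pytest.raises(ParameterError):
            DOEGrid(ranges={"c10": (10.0, 5.0), "k1": (1, 2), "k2": (1, 2)})
        with pytest.raises(ParameterError):
            DOEGrid(resolution={"c10": 1, "k1": 3, "k2": 3})

    def test_counts_bounds_and_truth_cell(self, small_truth):
        truth, _, sub = small_truth
        tc, tk1, tk2 = truth.c10[0], truth.k1[0], truth.k2[0]
        # grid that contains the exact truth point
        grid = DOEGrid(
            ranges={"c10": (tc / 10, tc * 10), "k1": (tk1 / 10, tk1 * 10),
                    "k2": (tk2 / 4, tk2 * 4)},
            resolution={"c10": 3, "k1": 3, "k2": 3},
        )
        bounds, records = run_doe(sub, grid, FAST)
        assert len(records) == 27  # exhaustive sweep
        best = min((r for r in records if np.isfinite(r["sse"])), key=lambda r: r["sse"])
        assert np.isclose(best["c10"], tc) and np.isclose(best["k1"], tk1)
        assert best["sse"] < 1e-12  # residual vanishes at the truth
        for p, full in (("c10", grid.ranges["c10"]), ("k1", grid.ranges["k1"])):
            lo, hi = bounds[p]
            assert full[0] - 1e-12 <= lo < hi <= full[1] + 1e-12


class TestPSO:
    def test_config_validation(self):
        with pytest.raises(ParameterError):
            PSOConfig(swarm_size=1)
        with pytest.raises(ParameterError):
            PSOConfig(inertia=-0.1)

    def test_residual_at_truth_is_tiny(self, small_truth):
        truth, _, sub = small_truth
        from scleramap.inverse import _objective_factory

        obj = _objective_factory(sub, FAST)
        sse, _ = obj(truth.c10[0], truth.k1[0], truth.k2[0])
        assert sse <= 1e-12

    def test_same_seed_identical_history(self, small_truth):
        truth, _, sub = small_truth
        bounds = {
            "c10": (truth.c10[0] / 3, truth.c10[0] * 3),
            "k1": (truth.k1[0] / 3, truth.k1[0] * 3),
            "k2": (truth.k2[0] / 3, truth.k2[0] * 3),
        }
        pso = PSOConfig(swarm_size=6, max_iterations=4, seed=11,
                        hybrid_polish=False, stall_iterations=10)
        r1 = optimize_subdomain(sub, bounds, pso, FAST)
        r2 = optimize_subdomain(sub, bounds, pso, FAST)
        assert r1.history == r2.history
        assert (r1.c10, r1.k1, r1.k2) == (r2.c10, r2.k1, r2.k2)

    def test_best_so_far_monotone_and_in_bounds(self, small_truth):
        truth, _, sub = small_truth
        bounds = {
            "c10": (truth.c10[0] / 3, truth.c10[0] * 3),
            "k1": (truth.k1[0] / 3, truth.k1[0] * 3),
            "k2": (truth.k2[0] / 3, truth.k2[0] * 3),
        }
        pso = PSOConfig(swarm_size=6, max_iterations=6, seed=1, hybrid_polish=False)
        res = optimize_subdomain(sub, bounds, pso, FAST)
        hist = np.asarray(res.history)
        assert (np.diff(hist) <= 1e-30).all()
        for p, v in zip(("c10", "k1", "k2"), (res.c10, res.k1, res.k2)):
            lo, hi = bounds[p]
            assert lo * (1 - 1e-9) <= v <= hi * (1 + 1e-9)


class TestMergeAndSmooth:
    def _results(self, values):
        return {
            sid: OptimizationResult(sid, c10, k1, k2, 0.0, [], {}, 0)
            for sid, (c10, k1, k2) in values.items()
        }

    def test_single_subdomain_uniform(self, strip_mesh):
        lab = SubdomainLabeling(np.ones(strip_mesh.n_triangles, int), np.empty(0), 1)
        adjacency = build_edge_adjacency(strip_mesh)
        pmap = merge_and_smooth_parameters(
            lab, self._results({1: (100.0, 1000.0, 50.0)}), adjacency, band_width=2
        )
        assert np.allclose(pmap.c10, 100.0) and np.allclose(pmap.k2, 50.0)

    def test_two_region_transition_monotone_and_bounded(self, strip_mesh):
        labels = np.ones(strip_mesh.n_triangles, int)
        x = strip_mesh.centroids()[:, 0]
        labels[x > 4.0] = 2
        lab = SubdomainLabeling(labels, np.array([0.5]), 2)
        adjacency = build_edge_adjacency(strip_mesh)
        pmap = merge_and_smooth_parameters(
            lab, self._results({1: (100.0, 500.0, 30.0), 2: (200.0, 900.0, 60.0)}),
            adjacency, band_width=2, iterations=10,
        )
        assert (pmap.c10 >= 100.0 - 1e-9).all() and (pmap.c10 <= 200.0 + 1e-9).all()
        band = (x > 2.0) & (x < 6.0)
        assert (pmap.c10[band & (labels == 1)] >= 100.0).all()
        order = np.argsort(x)
        # column-averaged profile is monotone across the interface
        prof = [pmap.c10[np.isclose(x, xv)].mean() for xv in np.unique(np.round(x, 6))]
        assert all(a <= b + 1e-9 for a, b in zip(prof, prof[1:]))
        assert 100.0 < pmap.c10[np.argmin(np.abs(x - 4.0))] < 200.0

    def test_zero_band_is_piecewise_constant(self, strip_mesh):
        labels = np.ones(strip_mesh.n_triangles, int)
        labels[strip_mesh.centroids()[:, 0] > 4.0] = 2
        lab = SubdomainLabeling(labels, np.array([0.5]), 2)
        adjacency = build_edge_adjacency(strip_mesh)
        pmap = merge_and_smooth_parameters(
            lab, self._results({1: (100.0, 500.0, 30.0), 2: (200.0, 900.0, 60.0)}),
            adjacency, band_width=0,
        )
        assert set(np.unique(pmap.c10)) == {100.0, 200.0}

    def test_missing_result_rejected(self, strip_mesh):
        labels = np.ones(strip_mesh.n_triangles, int)
        labels[0:2] = 2
        lab = SubdomainLabeling(labels, np.array([0.5]), 2)
        adjacency = build_edge_adjacency(strip_mesh)
        with pytest.raises(ParameterError):
            merge_and_smooth_parameters(
                lab, self._results({1: (100.0, 500.0, 30.0)}), adjacency
            )


class TestGlobalCheck:
    def test_self_consistency_zero_noise(self, fine_hemisphere):
        from scleramap.inverse import ParameterMap

        protocol = PressureProtocol()
        truth = make_ground_truth(fine_hemisphere, n_regions=2, seed=5, layout="bands")
        field = simulate_inflation_experiment(truth, protocol, noise_sigma=0.0, seed=0)
        pmap = ParameterMap(
            truth.element_param("c10"), truth.element_param("k1"), truth.element_param("k2")
        )
        report, _ = global_check(
            fine_hemisphere, pmap, truth.thickness, truth.fibers,
            truth.element_param("kappa"), protocol, field,
            SolverConfig(sub_increments=2), hole_margin="free",
        )
        assert report["mean_error_mm"] < 1e-6

    def test_noise_reflected_in_error(self, fine_hemisphere):
        from scleramap.inverse import ParameterMap

        protocol = PressureProtocol()
        truth = make_ground_truth(fine_hemisphere, n_regions=1, seed=5)
        pmap = ParameterMap(
            truth.element_param("c10"), truth.element_param("k1"), truth.element_param("k2")
        )
        sigma = 0.005
        errs = []
        for seed in range(3):
            field = simulate_inflation_experiment(truth, protocol, noise_sigma=sigma, seed=seed)
            report, _ = global_check(
                fine_hemisphere, pmap, truth.thickness, truth.fibers,
                truth.element_param("kappa"), protocol, field,
                SolverConfig(sub_increments=2), hole_margin="free",
            )
            errs.append(report["mean_error_mm"])
        # mean 3D-norm of N(0, sigma I3) is sigma*sqrt(8/pi) ~ 1.6 sigma
        assert all(0.5 * sigma < e < 2 * sigma for e in errs)
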