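"""Pipeline orchestration: simulate -> strain -> partition -> fit -> check.

Each stage writes its artifacts into the configured output directory and
appends an entry (config, seeds, input hashes, metrics) to a JSON run
manifest, so a finished run is reproducible from the manifest alone. Stages
can be resumed from cached artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as smio
from .config import RunConfig
from .errors import ConfigError
from .forward import PressureProtocol, SolverConfig
from .inverse import (
    DOEGrid,
    PSOConfig,
    global_check,
    merge_and_smooth_parameters,
    optimize_subdomain,
    run_doe,
)
from .kinematics import DisplacementField, strain_field
from .mesh import TriSurfaceMesh, build_edge_adjacency, generate_hemisphere_shell
from .subdomains import (
    extract_subdomain_problem,
    find_single_layer_regions,
    partition_by_strain_percentile,
    reassign_single_layer,
)
from .synthetic import circumferential_fibers, make_ground_truth, simulate_inflation_experiment

logger = logging.getLogger(__name__)

__all__ = ["Pipeline", "run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    def __init__(self, config: RunConfig, resume: bool = False):
        self.config = config
        self.resume = resume
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if resume and self.manifest_path.exists()
            else {"config": config.model_dump(), "stages": []}
        )

    # -- plumbing ------------------------------------------------------

    def _record(self, stage: str, **info):
        entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
        self.manifest["stages"].append(entry)
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, default=_json_default))

    def _protocol(self) -> PressureProtocol:
        p = self.config.protocol
        return PressureProtocol(p.reference_mmhg, tuple(p.steps_mmhg))

    def _solver_config(self, **kw) -> SolverConfig:
        s = self.config.solver
        base = dict(
            rtol=s.rtol,
            atol=s.atol,
            max_iterations=s.max_iterations,
            sub_increments=s.sub_increments,
            max_line_search=s.max_line_search,
            max_retries=s.max_retries,
        )
        base.update(kw)
        return SolverConfig(**base)

    # -- stages --------------------------------------------------------

    def simulate(self):
        """Generate a synthetic shell + noisy inflation experiment."""
        cfg = self.config
        mesh_file = self.out / "mesh.vtk"
        disp_file = self.out / "displacements.csv"
        truth_file = self.out / "truth.csv"
        if self.resume and mesh_file.exists() and disp_file.exists():
            logger.info("simulate: cached artifacts found, skipping")
            return mesh_file, disp_file
        g = cfg.geometry
        mesh = generate_hemisphere_shell(
            g.radius_mm, g.hole_radius_mm, g.target_edge_length_mm, seed=cfg.seed
        )
        truth = make_ground_truth(
            mesh,
            n_regions=cfg.simulate.n_regions,
            param_ranges={
                "c10": cfg.simulate.c10_range_kpa,
                "k1": cfg.simulate.k1_range_kpa,
                "k2": cfg.simulate.k2_range,
            },
            seed=cfg.seed,
            layout=cfg.simulate.layout,
            thickness=g.thickness_mm,
        )
        field = simulate_inflation_experiment(
            truth,
            self._protocol(),
            noise_sigma=cfg.simulate.noise_sigma_mm,
            seed=cfg.seed + 1,
            solver_config=self._solver_config(),
        )
        smio.write_mesh_bundle(
            mesh_file,
            mesh,
            cell_data={
                "thickness_mm": truth.thickness,
                "region": truth.region_labels.astype(float),
                "c10_true_kPa": truth.element_param("c10"),
                "k1_true_kPa": truth.element_param("k1"),
                "k2_true": truth.element_param("k2"),
                "kappa": truth.element_param("kappa"),
            },
        )
        smio.write_displacement_csv(disp_file, field.pressures_mmhg, field.u)
        smio.write_parameter_table(
            truth_file,
            [
                {
                    "subdomain_id": r + 1,
                    "C10_kPa": truth.c10[r],
                    "k1_kPa": truth.k1[r],
                    "k2": truth.k2[r],
                    "kappa": truth.kappa[r],
                }
                for r in range(truth.n_regions)
            ],
        )
        self._record(
            "simulate",
            seed=cfg.seed,
            noise_sigma_mm=cfg.simulate.noise_sigma_mm,
            mesh=str(mesh_file),
            mesh_sha=_sha256(mesh_file),
            displacements=str(disp_file),
            displacements_sha=_sha256(disp_file),
        )
        return mesh_file, disp_file

    def load_inputs(self):
        cfg = self.config
        mesh_path = cfg.mesh_path or str(self.out / "mesh.vtk")
        disp_path = cfg.displacements_path or str(self.out / "displacements.csv")
        if not Path(mesh_path).exists():
            raise ConfigError(f"mesh file not found: {mesh_path}")
        if not Path(disp_path).exists():
            raise ConfigError(f"displacement file not found: {disp_path}")
        mesh, node_data, cell_data = smio.read_mesh_bundle(mesh_path)
        pressures, u = smio.read_displacement_csv(disp_path)
        field = DisplacementField(pressures, u)
        return mesh, cell_data, field

    def partition(self, mesh: TriSurfaceMesh, field: DisplacementField):
        cfg = self.config.partition
        e1 = strain_field(
            mesh,
            field.u[-1],
            smooth_iterations=cfg.smooth_iterations,
            smooth_factor=cfg.smooth_factor,
        )
        labeling = partition_by_strain_percentile(
            e1, cfg.n_subdomains, None if cfg.edges is None else np.asarray(cfg.edges)
        )
        adjacency = build_edge_adjacency(mesh)
        strips = find_single_layer_regions(labeling, adjacency)
        labeling = reassign_single_layer(labeling, strips, e1, adjacency)
        if cfg.split_connected_components:
            from .subdomains import split_into_connected_components

            labeling = split_into_connected_components(labeling, adjacency)
        self._record(
            "partition",
            n_subdomains=cfg.n_subdomains,
            single_layer_regions_reassigned=len(strips),
            counts={int(k): int((labeling.labels == k).sum()) for k in range(1, labeling.K + 1)},
        )
        return e1, labeling, adjacency

    def fit(self, mesh, cell_data, field, labeling, adjacency):
        cfg = self.config
        thickness = cell_data.get("thickness_mm", np.full(mesh.n_triangles, cfg.geometry.thickness_mm))
        kappa = cell_data.get("kappa", np.full(mesh.n_triangles, 0.24))
        fibers = circumferential_fibers(mesh)
        protocol = self._protocol()
        grid = DOEGrid(
            ranges={
                "c10": cfg.doe.c10_range_kpa,
                "k1": cfg.doe.k1_range_kpa,
                "k2": cfg.doe.k2_range,
            },
            resolution=cfg.doe.resolution,
        )
        fast = self._solver_config(sub_increments=1, max_iterations=20, max_retries=1)
        results = {}
        for sid in range(1, labeling.K + 1):
            sub = extract_subdomain_problem(
                mesh, labeling, sid, field, thickness, fibers, kappa, protocol
            )
            bounds, _ = run_doe(sub, grid, fast)
            pso = PSOConfig(
                swarm_size=cfg.pso.swarm_size,
                max_iterations=cfg.pso.max_iterations,
                inertia=cfg.pso.inertia,
                cognitive=cfg.pso.cognitive,
                social=cfg.pso.social,
                ftol=cfg.pso.ftol,
                stall_iterations=cfg.pso.stall_iterations,
                seed=cfg.seed + sid,
                hybrid_polish=cfg.pso.hybrid_polish,
                polish_max_evals=cfg.pso.polish_max_evals,
            )
            res = optimize_subdomain(sub, bounds, pso, fast)
            results[sid] = res
            logger.info(
                "subdomain %d: C10=%.4g kPa k1=%.4g kPa k2=%.4g residual=%.3g mm^2",
                sid, res.c10, res.k1, res.k2, res.residual,
            )
        rows = [results[s].as_row() for s in sorted(results)]
        smio.write_parameter_table(self.out / "recovered_parameters.csv", rows)
        pmap = merge_and_smooth_parameters(
            labeling,
            results,
            adjacency,
            band_width=cfg.smoothing.band_width,
            iterations=cfg.smoothing.iterations,
        )
        self._record(
            "fit",
            results=rows,
            bounds={s: results[s].bounds for s in results},
            seeds={s: results[s].seed for s in results},
            evaluations={s: results[s].n_evaluations for s in results},
        )
        return results, pmap, thickness, kappa, fibers

    def check(self, mesh, pmap, thickness, kappa, fibers, field):
        report, result = global_check(
            mesh,
            pmap,
            thickness,
            fibers,
            kappa,
            self._protocol(),
            field,
            self._solver_config(),
            hole_margin=self.config.hole_margin,
        )
        smio.write_mesh_bundle(
            self.out / "global_check.vtk",
            mesh,
            node_data={"error_mm": report["per_node_error_mm"]},
            cell_data={"c10_kPa": pmap.c10, "k1_kPa": pmap.k1, "k2": pmap.k2},
        )
        self._record(
            "check",
            mean_error_mm=report["mean_error_mm"],
            max_error_mm=report["max_error_mm"],
            sse_per_node_mm2=report["sse_per_node_mm2"],
        )
        return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig, resume: bool = False, simulate_first: bool = None):
    """Execute the full workflow; returns (manifest dict, global-check report)."""
    pipe = Pipeline(config, resume=resume)
    need_sim = simulate_first
    if need_sim is None:
        need_sim = config.mesh_path is None or config.displacements_path is None
    if need_sim:
        pipe.simulate()
    mesh, cell_data, field = pipe.load_inputs()
    _, labeling, adjacency = pipe.partition(mesh, field)
    _, pmap, thickness, kappa, fibers = pipe.fit(mesh, cell_data, field, labeling, adjacency)
    report = pipe.check(mesh, pmap, thickness, kappa, fibers, field)
    return pipe.manifest, report
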