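"""Run configuration: schema-validated YAML with every tolerance and seed explicit."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    reference_mmhg: float = 5.0
    steps_mmhg: list[float] = [15.0, 30.0, 45.0]


class GeometryConfig(_Strict):
    radius_mm: float = 12.0
    hole_radius_mm: float = 1.75
    target_edge_length_mm: float = 1.25
    thickness_mm: float = 1.0


class SimulateConfig(_Strict):
    n_regions: int = 4
    layout: str = "sectors"
    noise_sigma_mm: float = 0.005
    c10_range_kpa: tuple[float, float] = (30.0, 150.0)
    k1_range_kpa: tuple[float, float] = (150.0, 1500.0)
    k2_range: tuple[float, float] = (20.0, 200.0)


class PartitionConfig(_Strict):
    n_subdomains: int = 4
    edges: list[float] | None = None
    smooth_iterations: int = 25
    smooth_factor: float = 0.5
    split_connected_components: bool = False


class SolverSettings(_Strict):
    rtol: float = 1e-8
    atol: float = 1e-10
    max_iterations: int = 50
    sub_increments: int = 2
    max_line_search: int = 10
    max_retries: int = 2


class DOESettings(_Strict):
    c10_range_kpa: tuple[float, float] = (5.0, 4.0e4)
    k1_range_kpa: tuple[float, float] = (1.0e-3, 4.0e4)
    k2_range: tuple[float, float] = (0.1, 300.0)
    resolution: dict[str, int] = {"c10": 7, "k1": 9, "k2": 4}


class PSOSettings(_Strict):
    swarm_size: int = 30
    max_iterations: int = 100
    inertia: float = 0.7298
    cognitive: float = 1.4962
    social: float = 1.4962
    ftol: float = 1e-10
    stall_iterations: int = 15
    hybrid_polish: bool = True
    polish_max_evals: int = 400


class SmoothingSettings(_Strict):
    band_width: int = 3
    iterations: int = 10


class RunConfig(_Strict):
    """Top-level run configuration; unknown keys are rejected."""

    mesh_path: str | None = None
    displacements_path: str | None = None
    inner_cloud_path: str | None = None
    output_dir: str = "scleramap_out"
    hole_margin: str = "prescribed"
    seed: int = 0

    protocol: ProtocolConfig = ProtocolConfig()
    geometry: GeometryConfig = GeometryConfig()
    simulate: SimulateConfig = SimulateConfig()
    partition: PartitionConfig = PartitionConfig()
    solver: SolverSettings = SolverSettings()
    doe: DOESettings = DOESettings()
    pso: PSOSettings = PSOSettings()
    smoothing: SmoothingSettings = SmoothingSettings()


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load YAML config (or defaults) and apply dotted-key overrides."""
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        try:
            data = yaml.safe_load(p.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML config {p}: {exc}") from exc
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        target = data
        parts = key.split(".")
        for part in parts[:-1]:
            target = target.setdefault(part, {})
        target[parts[-1]] = value
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
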