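"""Run configuration: one serialisable object per simulation.

Every source of randomness has an explicit seed (egg packing, mortality
assignment, boundary noise) and the full configuration round-trips through
YAML, so a run is reconstructable bit-for-bit from the config persisted next
to its outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .geometry import ChamberProfile
from .materials import (
    AIR,
    WATER,
    ConstituentPhase,
    EffectiveProperties,
    MixtureSpec,
    egg_properties,
    sand_effective_properties,
)
from .metabolism import (
    DEFAULT_CATEGORY_PROPORTIONS,
    DevRateCurve,
    MetabolicHeatCurve,
    Q10Params,
)
from .outcomes import HatchLogistic, TSDReactionNorm
from .synthetic import BoundaryScenario

__all__ = [
    "GeometryConfig",
    "MaterialsConfig",
    "SolverConfig",
    "MetabolismConfig",
    "OutcomesConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass(frozen=True)
class GeometryConfig:
    nest_depth_m: float = 0.60
    clutch_size: int = 51
    egg_diameter_m: float = 0.0467
    packing_seed: int = 0
    chamber_height_m: float = 0.31
    neck_radius_m: float = 0.09
    bulb_radius_m: float = 0.13
    bulb_semi_height_m: float = 0.12

    def chamber(self) -> ChamberProfile:
        return ChamberProfile(
            height=self.chamber_height_m,
            neck_radius=self.neck_radius_m,
            bulb_radius=self.bulb_radius_m,
            bulb_semi_height=self.bulb_semi_height_m,
        )


@dataclass(frozen=True)
class MaterialsConfig:
    """Field measurements plus constituent constants.

    Defaults are the published field values (beach dry bulk density
    1282.2 kg m-3 at 4.0% moisture; nest sand 1026.6 kg m-3) and the
    package's calibrated constituent constants (see the methods note).
    """

    beach_dry_bulk_density: float = 1282.2
    beach_moisture: float = 0.040
    nest_dry_bulk_density: float = 1026.6
    nest_moisture: float = 0.0392
    quartzite_density: float = 2650.0
    quartzite_conductivity: float = 5.57
    quartzite_heat_capacity: float = 479.37
    egg_density: float = 1000.0
    egg_conductivity: float = 0.6
    egg_heat_capacity: float = 4177.6

    def effective(self) -> dict[str, EffectiveProperties]:
        matrix = ConstituentPhase(
            "quartzite",
            self.quartzite_density,
            self.quartzite_conductivity,
            self.quartzite_heat_capacity,
        )
        beach = MixtureSpec(self.beach_dry_bulk_density, self.beach_moisture, matrix, WATER, AIR)
        nest = MixtureSpec(self.nest_dry_bulk_density, self.nest_moisture, matrix, WATER, AIR)
        return {
            "beach": sand_effective_properties(beach),
            "nest_sand": sand_effective_properties(nest),
            "egg": egg_properties(
                self.egg_density, self.egg_conductivity, self.egg_heat_capacity
            ),
        }


@dataclass(frozen=True)
class SolverConfig:
    cell_size_m: float = 0.02
    substeps: int = 1
    deposition: str = "point"
    footprint_radius_m: float | None = None  # default: chamber bulb radius
    snapshot_hours: tuple[int, ...] = ()


@dataclass(frozen=True)
class MetabolismConfig:
    t_opt_c: float = 33.5
    r_max_pct_per_h: float = 0.1
    sigma_below_c: float = 8.0
    sigma_above_c: float = 2.5
    h_max_mw: float = 65.0
    gamma: float = 4.0
    q10: float = 2.0
    t_ref_c: float = 29.5
    scaling: str = "q10"
    adjusted: bool = False  # gate fluxes by observed mortality categories
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    category_seed: int = 0

    def rate(self) -> DevRateCurve:
        return DevRateCurve(
            self.t_opt_c, self.r_max_pct_per_h, self.sigma_below_c, self.sigma_above_c
        )

    def heat_curve(self) -> MetabolicHeatCurve:
        return MetabolicHeatCurve(self.h_max_mw, self.gamma)

    def q10_params(self) -> Q10Params:
        return Q10Params(self.q10, self.t_ref_c)


@dataclass(frozen=True)
class OutcomesConfig:
    pivotal_temp_c: float = 30.3
    tsd_shape: float = -0.01
    hatch_inflection_c: float = 32.7
    hatch_slope: float = 1.0
    sex_mode: str = "tsp_mean"

    def norm(self) -> TSDReactionNorm:
        return TSDReactionNorm(self.pivotal_temp_c, self.tsd_shape)

    def logistic(self) -> HatchLogistic:
        return HatchLogistic(self.hatch_inflection_c, self.hatch_slope)


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    materials: MaterialsConfig = field(default_factory=MaterialsConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    metabolism: MetabolismConfig = field(default_factory=MetabolismConfig)
    outcomes: OutcomesConfig = field(default_factory=OutcomesConfig)
    scenario: BoundaryScenario = field(default_factory=BoundaryScenario)


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name == "snapshot_hours" and value is not None:
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML, filling unspecified fields with defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sections = {
        "geometry": GeometryConfig,
        "materials": MaterialsConfig,
        "solver": SolverConfig,
        "metabolism": MetabolismConfig,
        "outcomes": OutcomesConfig,
        "scenario": BoundaryScenario,
    }
    kwargs = {}
    for name, cls in sections.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section '{name}' must be a mapping")
        try:
            kwargs[name] = _from_dict(cls, section)
        except TypeError as exc:
            raise ValueError(f"config section '{name}': {exc}") from exc
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return RunConfig(**kwargs)


def config_to_yaml(config: RunConfig) -> str:
    data = asdict(config)
    data["solver"]["snapshot_hours"] = list(data["solver"]["snapshot_hours"])
    return yaml.safe_dump(data, sort_keys=True, default_flow_style=False)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(config_to_yaml(config))


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical YAML serialisation."""
    return hashlib.sha256(config_to_yaml(config).encode()).hexdigest()


def with_overrides(config: RunConfig, **sections) -> RunConfig:
    """Functional update: with_overrides(cfg, solver={'cell_size_m': 0.01})."""
    updates = {}
    for name, overrides in sections.items():
        current = getattr(config, name)
        updates[name] = replace(current, **overrides)
    return replace(config, **updates)
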