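"""Run configuration: one YAML document holding every tunable constant.

No physical constant is hard-coded at a call site; the CLI builds its
objects from a :class:`RunConfig` so a run is reproducible from its config
echo alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .forcing import DEFAULT_REFERENCE_PAR
from .mapping import DEFAULT_BANDS
from .melt import PhysicalConstants

__all__ = ["RunConfig", "load_config", "save_config"]


def _default_bands() -> list[dict]:
    return [
        {"name": b.name, "center": b.center, "lower": b.lower, "upper": b.upper}
        for b in DEFAULT_BANDS
    ]


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond its input files."""

    # physical constants
    par_conversion_umol_per_j: float = 4.57
    rho_air_kg_m3: float = 1.29
    cp_air_j_kg_k: float = 1005.0
    heat_transfer_coeff: float = 1.5e-3
    latent_heat_fusion_j_kg: float = 3.34e5
    water_density_kg_m3: float = 1000.0
    # regression (published coefficients as defaults; refit from a sample
    # table by pointing sample_table at a density-IRF CSV)
    regression_slope: float = 5.52
    regression_intercept: float = -24.03
    reference_par: float = DEFAULT_REFERENCE_PAR
    sample_table: str | None = None
    # surface
    surface_label: str = "weathering_crust"
    surface_albedo: float = 0.55
    surface_density_kg_m3: float = 500.0
    # mapping
    bands: list[dict] = field(default_factory=_default_bands)
    classifier_band_names: list[str] = field(default_factory=lambda: ["B4", "B5", "B6"])
    pixel_size_m: float = 1.6
    # scenario
    cell_density_per_ml: float = 2.5e5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "par_conversion_umol_per_j",
            "rho_air_kg_m3",
            "cp_air_j_kg_k",
            "heat_transfer_coeff",
            "latent_heat_fusion_j_kg",
            "water_density_kg_m3",
            "reference_par",
            "pixel_size_m",
            "cell_density_per_ml",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"config constant {name} must be > 0")

    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(
            rho_air=self.rho_air_kg_m3,
            cp_air=self.cp_air_j_kg_k,
            ch0=self.heat_transfer_coeff,
            latent_heat_fusion=self.latent_heat_fusion_j_kg,
            water_density=self.water_density_kg_m3,
            par_conversion=self.par_conversion_umol_per_j,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
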