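"""Detected centers -> cell density (cells/mm^2) -> total cells per vessel."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection import DetectionResult

#: vendor-standard growth areas, cm^2
VESSEL_AREAS_CM2 = {"well_6": 9.6, "T25": 25.0, "T75": 75.0}


@dataclass(frozen=True)
class FieldGeometry:
    width_px: int
    height_px: int
    um_per_px_working: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.um_per_px_working <= 0:
            raise ValueError("FieldGeometry fields must be positive")

    @property
    def field_area_mm2(self) -> float:
        return self.width_px * self.height_px * (self.um_per_px_working / 1000.0) ** 2


@dataclass(frozen=True)
class VesselSpec:
    vessel_type: str = "well_6"
    growth_area_cm2: float | None = None

    def __post_init__(self) -> None:
        if self.vessel_type not in VESSEL_AREAS_CM2 and self.vessel_type != "custom":
            raise ValueError(f"unknown vessel_type {self.vessel_type!r}")
        if self.vessel_type == "custom" and (self.growth_area_cm2 or 0) <= 0:
            raise ValueError("custom vessel requires positive growth_area_cm2")
        if self.growth_area_cm2 is not None and self.growth_area_cm2 <= 0:
            raise ValueError("growth_area_cm2 must be positive")

    @property
    def area_cm2(self) -> float:
        if self.growth_area_cm2 is not None:
            return self.growth_area_cm2
        return VESSEL_AREAS_CM2[self.vessel_type]


@dataclass
class DensityEstimate:
    image_id: str
    n_centers: int
    density_cells_per_mm2: float


@dataclass
class TotalCellEstimate:
    mean_density: float      # cells / mm^2
    total_cells: float
    n_fields: int
    passage: int = 0


def density_from_centers(det: DetectionResult, geom: FieldGeometry) -> DensityEstimate:
    """cells/mm^2 in one field: center count over field area."""
    return DensityEstimate(
        image_id=det.image_id,
        n_centers=det.n_centers,
        density_cells_per_mm2=det.n_centers / geom.field_area_mm2,
    )


def total_cells(
    estimates: Sequence[DensityEstimate], vessel: VesselSpec, passage: int = 0
) -> TotalCellEstimate:
    """Mean field density extrapolated to the vessel growth area (1 cm^2 = 100 mm^2)."""
    if len(estimates) == 0:
        raise ValueError("total_cells requires at least one field")
    mean_density = float(np.mean([e.density_cells_per_mm2 for e in estimates]))
    return TotalCellEstimate(
        mean_density=mean_density,
        total_cells=mean_density * vessel.area_cm2 * 100.0,
        n_fields=len(estimates),
        passage=passage,
    )
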