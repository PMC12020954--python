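"""Stage 1: per-eye band thickness maps, loss masks/areas, SDD volumetry.

Three outer retinal bands are quantified from the five segmentation
surfaces:

* ``ELM_MZ`` -- external limiting membrane plus myoid zone, from the ELM to
  the EZ inner boundary;
* ``EZ`` -- ellipsoid-zone band including the interdigitation zone, from the
  EZ inner boundary to the RPE inner boundary;
* ``RPE`` -- retinal pigment epithelium band, from its inner to its outer
  boundary (material posterior to the outer boundary -- basal laminar
  deposits, drusen, Bruch's membrane -- is excluded by construction).

Thickness at atrophic columns is *missing*, not zero, so thickness means
describe surviving tissue only; loss is reported separately as an area.
Subretinal drusenoid deposit (SDD) thickness is the gap between the EZ
outer and RPE inner boundaries where it exceeds a strict 4 um threshold
(one axial pixel), which excludes diffuse stage-1-like material and guards
against segmentation error.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import (
    ScanGeometry,
    column_cell_area_mm2,
    column_cell_area_um2,
    um3_to_nl,
)
from .surfaces import EnFaceMap, SurfaceSet

__all__ = [
    "BAND_DEFINITIONS",
    "BANDS",
    "QuantResult",
    "thickness_map",
    "loss_mask",
    "loss_area_mm2",
    "sdd_thickness_map",
    "sdd_volume_nl",
    "quantify",
    "DEFAULT_SDD_THRESHOLD_UM",
]

#: band label -> (anterior surface, posterior surface); fixed and exhaustive
BAND_DEFINITIONS: dict[str, tuple[str, str]] = {
    "ELM_MZ": ("ELM", "EZ_inner"),
    "EZ": ("EZ_inner", "RPE_inner"),
    "RPE": ("RPE_inner", "RPE_outer"),
}

BANDS = tuple(BAND_DEFINITIONS)

DEFAULT_SDD_THRESHOLD_UM = 4.0


def thickness_map(surfaces: SurfaceSet, band: str) -> EnFaceMap:
    """Band thickness (um): posterior minus anterior surface per column.

    Missing wherever either boundary is missing; for the EZ band also at
    SDD-disrupted columns, which count as EZ loss by contract.  Validates
    the surface ordering first, so values are never negative.
    """
    if band not in BAND_DEFINITIONS:
        raise KeyError(f"unknown band {band!r}; expected one of {BANDS}")
    surfaces.validate()
    anterior, posterior = BAND_DEFINITIONS[band]
    values = surfaces.surfaces[posterior] - surfaces.surfaces[anterior]
    if band == "EZ":
        values = values.copy()
        values[surfaces.sdd_disrupted] = np.nan
    return EnFaceMap(
        values=values,
        quantity_label=f"{band}_thickness_um",
        geometry=surfaces.geometry,
        fovea_center=surfaces.fovea_center,
    )


def loss_mask(surfaces: SurfaceSet, band: str) -> EnFaceMap:
    """Indicator map of band loss: 1 where a defining boundary is missing.

    EZ loss additionally includes columns carrying the SDD-disruption flag
    (deposits that visibly displaced the EZ), even though the surfaces are
    present there.
    """
    if band not in BAND_DEFINITIONS:
        raise KeyError(f"unknown band {band!r}; expected one of {BANDS}")
    surfaces.validate()
    anterior, posterior = BAND_DEFINITIONS[band]
    lost = np.isnan(surfaces.surfaces[anterior]) | np.isnan(
        surfaces.surfaces[posterior]
    )
    if band == "EZ":
        lost = lost | surfaces.sdd_disrupted
    return EnFaceMap(
        values=lost.astype(float),
        quantity_label=f"{band}_loss",
        geometry=surfaces.geometry,
        fovea_center=surfaces.fovea_center,
    )


def loss_area_mm2(mask: EnFaceMap, geometry: ScanGeometry | None = None) -> float:
    """Loss area: number of flagged columns times the per-column cell area."""
    geometry = geometry or mask.geometry
    count = float(np.nansum(mask.values))
    return count * column_cell_area_mm2(geometry)


def sdd_thickness_map(
    surfaces: SurfaceSet, threshold_um: float = DEFAULT_SDD_THRESHOLD_UM
) -> EnFaceMap:
    """SDD thickness (um): the EZ-outer to RPE-inner gap where it exceeds
    ``threshold_um`` (strictly), else 0; missing where either boundary is
    missing.  Sub-threshold gaps are tolerated as 0 rather than errors.
    """
    surfaces.validate()
    gap = surfaces.surfaces["RPE_inner"] - surfaces.surfaces["EZ_outer"]
    values = np.where(gap > threshold_um, gap, 0.0)
    values[np.isnan(gap)] = np.nan
    return EnFaceMap(
        values=values,
        quantity_label="sdd_thickness_um",
        geometry=surfaces.geometry,
        fovea_center=surfaces.fovea_center,
    )


def sdd_volume_nl(
    sdd_map: EnFaceMap,
    geometry: ScanGeometry | None = None,
    region_mask: np.ndarray | None = None,
) -> float:
    """Integrate an SDD thickness map to a volume in nanolitres.

    ``region_mask`` optionally restricts the sum to a boolean subregion of
    the lattice (e.g. one ETDRS subfield).
    """
    geometry = geometry or sdd_map.geometry
    values = sdd_map.values
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != values.shape:
            raise ValueError(
                f"region mask shape {region_mask.shape} does not match "
                f"map shape {values.shape}"
            )
        values = np.where(region_mask, values, np.nan)
    total_um3 = float(np.nansum(values)) * column_cell_area_um2(geometry)
    return um3_to_nl(total_um3)


@dataclasses.dataclass
class QuantResult:
    """Per-acquisition quantification bundle.

    ``thickness`` and ``loss`` map each band label to an en-face map;
    ``loss_area_mm2`` holds whole-field loss areas; ``sdd_volume_nl`` the
    whole-field SDD volume.
    """

    eye_id: str
    patient_id: str
    device_label: str
    geometry: ScanGeometry
    fovea_center: tuple[int, int]
    thickness: dict[str, EnFaceMap]
    loss: dict[str, EnFaceMap]
    loss_area_mm2: dict[str, float]
    sdd_thickness: EnFaceMap
    sdd_volume_nl: float

    def mean_thickness_um(self, band: str) -> float:
        """Whole-field mean band thickness over surviving (non-missing) columns."""
        values = self.thickness[band].values
        if np.all(np.isnan(values)):
            return float("nan")
        return float(np.nanmean(values))


def quantify(
    surfaces: SurfaceSet, sdd_threshold_um: float = DEFAULT_SDD_THRESHOLD_UM
) -> QuantResult:
    """Run the full stage-1 quantification for one acquisition.

    Outputs depend only on the um-valued surfaces and the lattice
    geometry -- never on the device label, which is carried through as
    metadata only.
    """
    surfaces.validate()
    thickness = {band: thickness_map(surfaces, band) for band in BANDS}
    loss = {band: loss_mask(surfaces, band) for band in BANDS}
    areas = {band: loss_area_mm2(loss[band]) for band in BANDS}
    sdd = sdd_thickness_map(surfaces, threshold_um=sdd_threshold_um)
    return QuantResult(
        eye_id=surfaces.eye_id,
        patient_id=surfaces.patient_id,
        device_label=surfaces.device_label,
        geometry=surfaces.geometry,
        fovea_center=surfaces.fovea_center,
        thickness=thickness,
        loss=loss,
        loss_area_mm2=areas,
        sdd_thickness=sdd,
        sdd_volume_nl=sdd_volume_nl(sdd),
    )
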