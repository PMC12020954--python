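"""Stage 2: fovea-centered ETDRS-grid sectorization and subfield summaries.

The ETDRS grid consists of concentric circles of 1, 3 and 6 mm diameter
around the fovea -- the central subfield, the parafoveal ring (1-3 mm) and
the perifoveal ring (3-6 mm) -- with the two rings divided into superior,
nasal, inferior and temporal quadrants along the +-45 degree diagonals.
Distances are computed from column centers in physical millimetres using
the anisotropic lattice spacings (A-scan pitch of a few micrometres versus
B-scan pitch of ~122 um); no isotropy is assumed.

Relative losses are normalized to the *nominal* full ring areas (0.79,
6.28, 21.21 mm^2) even though a 20 degree field slightly clips the 6-mm
circle -- the covered fraction is available as a diagnostic.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .bands import BANDS, QuantResult, sdd_volume_nl
from .geometry import ScanGeometry, column_cell_area_mm2, column_cell_area_um2
from .surfaces import EnFaceMap

__all__ = [
    "EtdrsGrid",
    "RINGS",
    "QUADRANTS",
    "DEFAULT_RING_RADII_MM",
    "subfield_areas_mm2",
    "quadrant_area_mm2",
    "assign_subfield",
    "ring_quadrant_labels",
    "summarize_subfields",
    "sdd_distribution_map",
    "covered_fraction",
]

RINGS = ("center", "parafoveal", "perifoveal")
QUADRANTS = ("superior", "nasal", "inferior", "temporal")
DEFAULT_RING_RADII_MM = (0.5, 1.5, 3.0)


@dataclasses.dataclass(frozen=True)
class EtdrsGrid:
    """Fovea-centered ETDRS grid: ring radii (mm), diagonal quadrant
    boundaries, and the laterality that maps image left/right onto
    temporal/nasal."""

    fovea_center: tuple[int, int]
    ring_radii_mm: tuple[float, float, float] = DEFAULT_RING_RADII_MM
    laterality: str = "OD"

    def __post_init__(self) -> None:
        r = self.ring_radii_mm
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError(f"ring radii must be strictly increasing, got {r}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"unknown laterality {self.laterality!r}")


def subfield_areas_mm2(
    ring_radii_mm: tuple[float, float, float] = DEFAULT_RING_RADII_MM,
    rounded: bool = True,
) -> dict[str, float]:
    """Nominal areas of the three ring subfields.

    With the standard radii these are 0.79, 6.28 and 21.21 mm^2 at 2-decimal
    reporting precision; pass ``rounded=False`` for the unrounded values
    used internally for normalization.
    """
    r0, r1, r2 = ring_radii_mm
    areas = {
        "center": math.pi * r0**2,
        "parafoveal_ring": math.pi * (r1**2 - r0**2),
        "perifoveal_ring": math.pi * (r2**2 - r1**2),
    }
    if rounded:
        return {k: round(v, 2) for k, v in areas.items()}
    return areas


def quadrant_area_mm2(
    ring_radii_mm: tuple[float, float, float] = DEFAULT_RING_RADII_MM
) -> float:
    """Nominal area of one merged (parafoveal + perifoveal) quadrant."""
    areas = subfield_areas_mm2(ring_radii_mm, rounded=False)
    return (areas["parafoveal_ring"] + areas["perifoveal_ring"]) / 4.0


def _offsets_mm(
    geometry: ScanGeometry, fovea_center: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(x_img, y) column-center offsets from the fovea in mm.

    x_img is positive toward the right of the en-face image, y positive
    superiorly (B-scan 0 is the inferior-most scan).
    """
    b_f, a_f = fovea_center
    x = (np.arange(geometry.n_ascans) - a_f) * geometry.lateral_spacing_um / 1000.0
    y = (np.arange(geometry.n_bscans) - b_f) * geometry.bscan_spacing_um / 1000.0
    return np.meshgrid(x, y)


def ring_quadrant_labels(
    grid: EtdrsGrid, geometry: ScanGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (ring, quadrant) label arrays for the whole lattice.

    ring: ``"center"``/``"parafoveal"``/``"perifoveal"``/``"outside"``
    (half-open radius bins [0, r0), [r0, r1), [r1, r2)); quadrant by angle
    in the anatomic frame with half-open bins at the +-45 degree diagonals
    (a column exactly on a boundary joins the counter-clockwise quadrant).
    """
    x_img, y = _offsets_mm(geometry, grid.fovea_center)
    x_nasal = x_img if grid.laterality == "OD" else -x_img
    r = np.hypot(x_nasal, y)
    r0, r1, r2 = grid.ring_radii_mm

    ring = np.full(r.shape, "outside", dtype=object)
    ring[r < r2] = "perifoveal"
    ring[r < r1] = "parafoveal"
    ring[r < r0] = "center"

    ang = np.degrees(np.arctan2(y, x_nasal))
    quadrant = np.full(r.shape, "temporal", dtype=object)
    quadrant[(ang >= -45.0) & (ang < 45.0)] = "nasal"
    quadrant[(ang >= 45.0) & (ang < 135.0)] = "superior"
    quadrant[(ang >= -135.0) & (ang < -45.0)] = "inferior"
    return ring, quadrant


def assign_subfield(
    bscan_idx: int, ascan_idx: int, grid: EtdrsGrid, geometry: ScanGeometry
) -> str:
    """Subfield label of one lattice column.

    Returns ``"center"``, ``"<ring>_<quadrant>"`` (e.g.
    ``"parafoveal_superior"``) or ``"outside"``.
    """
    shape = geometry.shape
    if not (0 <= bscan_idx < shape[0] and 0 <= ascan_idx < shape[1]):
        raise ValueError(f"column ({bscan_idx}, {ascan_idx}) outside lattice {shape}")
    ring, quadrant = ring_quadrant_labels(grid, geometry)
    ring_label = ring[bscan_idx, ascan_idx]
    if ring_label in ("center", "outside"):
        return str(ring_label)
    return f"{ring_label}_{quadrant[bscan_idx, ascan_idx]}"


def covered_fraction(grid: EtdrsGrid, geometry: ScanGeometry) -> dict[str, float]:
    """Fraction of each nominal ring area covered by lattice columns.

    A 20 degree field (~5.86 mm) slightly clips the 6-mm circle; this
    diagnostic quantifies the clipped share per ring.
    """
    ring, _ = ring_quadrant_labels(grid, geometry)
    cell = column_cell_area_mm2(geometry)
    nominal = subfield_areas_mm2(grid.ring_radii_mm, rounded=False)
    key = {"center": "center", "parafoveal": "parafoveal_ring",
           "perifoveal": "perifoveal_ring"}
    return {
        r: float((ring == r).sum()) * cell / nominal[key[r]] for r in RINGS
    }


def summarize_subfields(quant: QuantResult, grid: EtdrsGrid) -> pd.DataFrame:
    """Per-subfield summaries of one quantified acquisition (tidy layout).

    Rows carry (eye_id, device, subfield, band, metric, value) with:

    * per ring subfield and per band: ``mean_thickness_um`` over surviving
      columns, ``abs_loss_mm2`` (loss columns x cell area) and
      ``rel_loss_pct`` (absolute loss / nominal subfield area x 100);
    * whole-field rows per band plus whole-field ``sdd_volume_nl``;
    * SDD volumes for the central subfield and the four merged
      (parafoveal + perifoveal) quadrants, with an area-normalized
      ``sdd_nl_per_mm2`` companion for region comparisons.
    """
    geometry = quant.geometry
    if grid.fovea_center != tuple(quant.fovea_center):
        raise ValueError(
            f"grid fovea {grid.fovea_center} does not match quantification "
            f"fovea {tuple(quant.fovea_center)}"
        )
    ring, quadrant = ring_quadrant_labels(grid, geometry)
    cell_mm2 = column_cell_area_mm2(geometry)
    nominal = subfield_areas_mm2(grid.ring_radii_mm, rounded=False)
    quad_area = quadrant_area_mm2(grid.ring_radii_mm)
    center_area = nominal["center"]

    rows: list[tuple] = []
    meta = (quant.eye_id, quant.device_label)

    masks = {
        "center": ring == "center",
        "parafoveal_ring": ring == "parafoveal",
        "perifoveal_ring": ring == "perifoveal",
    }
    for band in BANDS:
        thick = quant.thickness[band].values
        lost = quant.loss[band].values
        for subfield, mask in masks.items():
            t_vals = thick[mask]
            mean_t = float(np.nanmean(t_vals)) if np.any(~np.isnan(t_vals)) else np.nan
            abs_loss = float(np.nansum(lost[mask])) * cell_mm2
            rel = abs_loss / nominal[subfield] * 100.0
            rows += [
                (*meta, subfield, band, "mean_thickness_um", mean_t),
                (*meta, subfield, band, "abs_loss_mm2", abs_loss),
                (*meta, subfield, band, "rel_loss_pct", rel),
            ]
        mean_whole = quant.mean_thickness_um(band)
        rows += [
            (*meta, "whole_field", band, "mean_thickness_um", mean_whole),
            (*meta, "whole_field", band, "abs_loss_mm2", quant.loss_area_mm2[band]),
        ]

    rows.append((*meta, "whole_field", "SDD", "sdd_volume_nl", quant.sdd_volume_nl))
    v_center = sdd_volume_nl(quant.sdd_thickness, region_mask=masks["center"])
    rows += [
        (*meta, "center", "SDD", "sdd_volume_nl", v_center),
        (*meta, "center", "SDD", "sdd_nl_per_mm2", v_center / center_area),
    ]
    in_rings = (ring == "parafoveal") | (ring == "perifoveal")
    for q in QUADRANTS:
        region = in_rings & (quadrant == q)
        v = sdd_volume_nl(quant.sdd_thickness, region_mask=region)
        rows += [
            (*meta, q, "SDD", "sdd_volume_nl", v),
            (*meta, q, "SDD", "sdd_nl_per_mm2", v / quad_area),
        ]
    return pd.DataFrame(
        rows, columns=["eye_id", "device", "subfield", "band", "metric", "value"]
    )


def sdd_distribution_map(quants: list[QuantResult]) -> EnFaceMap:
    """Cohort-average en-face SDD volume per column (um^3).

    Lattices are shifted so the fovea centers coincide and cropped to the
    common extent; the per-column mean over eyes of SDD thickness times
    cell area is returned.  Columns missing in an eye (atrophy) are
    excluded from that column's mean.
    """
    if not quants:
        raise ValueError("empty cohort")
    g0 = quants[0].geometry
    for q in quants:
        g = q.geometry
        if (
            abs(g.lateral_spacing_um - g0.lateral_spacing_um) > 1e-9
            or abs(g.bscan_spacing_um - g0.bscan_spacing_um) > 1e-9
        ):
            raise ValueError("all eyes must share the lattice spacings")

    left = min(q.fovea_center[1] for q in quants)
    right = min(q.geometry.n_ascans - 1 - q.fovea_center[1] for q in quants)
    below = min(q.fovea_center[0] for q in quants)
    above = min(q.geometry.n_bscans - 1 - q.fovea_center[0] for q in quants)

    stack = []
    for q in quants:
        b_f, a_f = q.fovea_center
        window = q.sdd_thickness.values[
            b_f - below : b_f + above + 1, a_f - left : a_f + right + 1
        ]
        stack.append(window * column_cell_area_um2(q.geometry))
    import warnings

    with warnings.catch_warnings():
        # columns atrophic in every eye have no SDD value: keep them NaN
        warnings.filterwarnings("ignore", "Mean of empty slice")
        mean = np.nanmean(np.stack(stack), axis=0)

    n_a = left + right + 1
    n_b = below + above + 1
    # shrink fov_deg so the lateral spacing of the cropped lattice is preserved
    geometry = dataclasses.replace(
        g0,
        n_ascans=n_a,
        n_bscans=n_b,
        fov_deg=g0.lateral_spacing_um * (n_a - 1) / (g0.mm_per_deg * 1000.0),
        device_label="cohort",
    )
    return EnFaceMap(
        values=mean,
        quantity_label="mean_sdd_volume_um3_per_column",
        geometry=geometry,
        fovea_center=(below, left),
    )
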