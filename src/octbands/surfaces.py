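"""Segmentation-surface containers and en-face maps.

A :class:`SurfaceSet` holds the five manually corrected axial surfaces of
the outer retina -- external limiting membrane (ELM), inner and outer
boundaries of the ellipsoid-zone band (EZ), and inner and outer boundaries
of the retinal pigment epithelium band (RPE) -- on the en-face lattice of
one acquisition.  Axial positions are micrometres from a common volume
reference and increase posteriorly, so anterior surfaces have smaller
values.  NaN marks a missing surface segment, which encodes loss of the
corresponding band (atrophy); zero is a legal measured position and never
means "missing".
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import ScanGeometry, make_geometry

__all__ = [
    "SURFACE_NAMES",
    "SurfaceSet",
    "EnFaceMap",
    "SurfaceOrderingError",
    "subsample_bscans",
]

#: anterior-to-posterior order of the five segmentation surfaces
SURFACE_NAMES = ("ELM", "EZ_inner", "EZ_outer", "RPE_inner", "RPE_outer")

#: band boundaries that must be missing together (a band cannot lose
#: one boundary only)
_PAIRED = (("EZ_inner", "EZ_outer"), ("RPE_inner", "RPE_outer"))


class SurfaceOrderingError(ValueError):
    """Raised when surfaces violate the anterior-to-posterior ordering."""


@dataclasses.dataclass
class EnFaceMap:
    """Fovea-registered 2-D scalar field on the A-scan x B-scan lattice.

    ``values`` has shape ``(n_bscans, n_ascans)``; NaN marks missing
    columns (e.g. atrophic columns on a thickness map).
    """

    values: np.ndarray
    quantity_label: str
    geometry: ScanGeometry
    fovea_center: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"map shape {self.values.shape} does not match geometry "
                f"shape {self.geometry.shape}"
            )

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclasses.dataclass
class SurfaceSet:
    """Five axial surfaces (um) of one eye on one device.

    ``surfaces`` maps each name in :data:`SURFACE_NAMES` to an array of
    shape ``(n_bscans, n_ascans)``.  ``sdd_disrupted`` flags columns where
    a subretinal drusenoid deposit visibly disrupted the EZ/ELM; such
    columns count as EZ loss even though the surfaces are present.
    """

    geometry: ScanGeometry
    surfaces: dict[str, np.ndarray]
    fovea_center: tuple[int, int]
    eye_id: str = "eye"
    patient_id: str = "patient"
    device_label: str = "standard"
    sdd_disrupted: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.geometry.shape
        missing = [s for s in SURFACE_NAMES if s not in self.surfaces]
        if missing:
            raise ValueError(f"surfaces missing: {missing}")
        self.surfaces = {
            name: np.asarray(self.surfaces[name], dtype=float)
            for name in SURFACE_NAMES
        }
        for name, arr in self.surfaces.items():
            if arr.shape != shape:
                raise ValueError(
                    f"surface {name} has shape {arr.shape}, expected {shape}"
                )
        if self.sdd_disrupted is None:
            self.sdd_disrupted = np.zeros(shape, dtype=bool)
        else:
            self.sdd_disrupted = np.asarray(self.sdd_disrupted, dtype=bool)
            if self.sdd_disrupted.shape != shape:
                raise ValueError("sdd_disrupted shape does not match lattice")
        b, a = self.fovea_center
        if not (0 <= b < shape[0] and 0 <= a < shape[1]):
            raise ValueError(
                f"fovea_center {self.fovea_center} outside lattice {shape}"
            )

    def validate(self, atol: float = 1e-6) -> None:
        """Check missing-pair consistency and the ordering invariant.

        Where two surfaces are both present at a column the anterior one
        must not lie posterior to the other (within ``atol``).  Violations
        signal corrupt segmentation and raise :class:`SurfaceOrderingError`
        with the offending columns.
        """
        for inner, outer in _PAIRED:
            mism = np.isnan(self.surfaces[inner]) != np.isnan(self.surfaces[outer])
            if mism.any():
                b, a = np.argwhere(mism)[0]
                raise ValueError(
                    f"{inner}/{outer} missingness differs at column "
                    f"(bscan={b}, ascan={a}): a band cannot have one boundary only"
                )
        for i, upper in enumerate(SURFACE_NAMES[:-1]):
            for lower in SURFACE_NAMES[i + 1 :]:
                u, l = self.surfaces[upper], self.surfaces[lower]
                bad = np.zeros(self.geometry.shape, dtype=bool)
                both = ~np.isnan(u) & ~np.isnan(l)
                bad[both] = u[both] > l[both] + atol
                if bad.any():
                    b, a = np.argwhere(bad)[0]
                    raise SurfaceOrderingError(
                        f"{upper} lies posterior to {lower} at column "
                        f"(bscan={b}, ascan={a}): "
                        f"{u[b, a]:.3f} > {l[b, a]:.3f} um"
                    )

    def copy(self) -> "SurfaceSet":
        return SurfaceSet(
            geometry=self.geometry,
            surfaces={k: v.copy() for k, v in self.surfaces.items()},
            fovea_center=tuple(self.fovea_center),
            eye_id=self.eye_id,
            patient_id=self.patient_id,
            device_label=self.device_label,
            sdd_disrupted=self.sdd_disrupted.copy(),
        )


def subsample_bscans(surfaces: SurfaceSet, step: int = 2) -> SurfaceSet:
    """Keep every ``step``-th B-scan (indices 0, step, 2*step, ...).

    Emulates quantifying 49 manually corrected B-scans out of a 97 B-scan
    acquisition: the retained scans represent proportionally wider slabs,
    so ``bscan_spacing_um`` is multiplied by ``step``.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    g = surfaces.geometry
    idx = np.arange(0, g.n_bscans, step)
    new_geometry = make_geometry(
        fov_deg=g.fov_deg,
        n_ascans=g.n_ascans,
        n_bscans=len(idx),
        mm_per_deg=g.mm_per_deg,
        bscan_spacing_um=g.bscan_spacing_um * step,
        axial_pitch_um=g.axial_pitch_um,
        laterality=g.laterality,
        device_label=g.device_label,
    )
    b_f, a_f = surfaces.fovea_center
    new_b = int(np.argmin(np.abs(idx - b_f)))
    return SurfaceSet(
        geometry=new_geometry,
        surfaces={k: v[idx].copy() for k, v in surfaces.surfaces.items()},
        fovea_center=(new_b, a_f),
        eye_id=surfaces.eye_id,
        patient_id=surfaces.patient_id,
        device_label=surfaces.device_label,
        sdd_disrupted=surfaces.sdd_disrupted[idx].copy(),
    )
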