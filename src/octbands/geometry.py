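"""Lattice geometry and physical calibration of an OCT volume.

An acquisition is a stack of ``n_bscans`` cross-sectional B-scans, each made
of ``n_ascans`` axial profiles (A-scans).  All en-face quantities in this
package live on the resulting ``n_bscans x n_ascans`` lattice; this module
holds the calibration that turns lattice columns into physical millimetres
and cubic micrometres.

Conventions (documented, configurable where it matters):

* Indices are 0-based.  B-scan 0 is the inferior-most scan; A-scan 0 is the
  leftmost column of the en-face image.
* Lateral A-scan spacing is ``fov_um / (n_ascans - 1)`` -- ``n_ascans``
  samples span the field of view with ``n_ascans - 1`` intervals; likewise
  for the B-scan direction.
* Each B-scan represents a slab of width ``bscan_spacing_um`` and each
  A-scan a strip of width the lateral spacing, so loss areas and volumes
  are rectangle-rule sums of per-column cells.
* Surfaces are stored in micrometres; ``axial_pitch_um`` exists only to
  convert pixel-valued inputs on ingestion.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

__all__ = [
    "ScanGeometry",
    "make_geometry",
    "column_cell_area_mm2",
    "column_cell_area_um2",
    "um3_to_nl",
    "LATERALITIES",
]

LATERALITIES = ("OD", "OS")

#: keys of the JSON sidecar, in serialization order
_GEOMETRY_KEYS = (
    "n_ascans",
    "n_bscans",
    "fov_deg",
    "mm_per_deg",
    "bscan_spacing_um",
    "axial_pitch_um",
    "laterality",
    "device_label",
)


def _require_positive_finite(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclasses.dataclass(frozen=True)
class ScanGeometry:
    """Lattice and physical calibration of one OCT volume.

    The default lateral calibration of 0.293 mm/degree makes the 48
    inter-B-scan intervals of a 20 degree, 49 B-scan cube equal 122.08 um,
    i.e. the conventional "122 um spacing" of that protocol.
    """

    n_ascans: int = 1024
    n_bscans: int = 49
    fov_deg: float = 20.0
    mm_per_deg: float = 0.293
    bscan_spacing_um: float = 5860.0 / 48.0
    axial_pitch_um: float | None = None
    laterality: str = "OD"
    device_label: str = "standard"

    def __post_init__(self) -> None:
        if int(self.n_ascans) != self.n_ascans or self.n_ascans < 2:
            raise ValueError(f"n_ascans must be an integer >= 2, got {self.n_ascans!r}")
        if int(self.n_bscans) != self.n_bscans or self.n_bscans < 2:
            raise ValueError(f"n_bscans must be an integer >= 2, got {self.n_bscans!r}")
        _require_positive_finite("fov_deg", self.fov_deg)
        _require_positive_finite("mm_per_deg", self.mm_per_deg)
        _require_positive_finite("bscan_spacing_um", self.bscan_spacing_um)
        if self.axial_pitch_um is not None:
            _require_positive_finite("axial_pitch_um", self.axial_pitch_um)
        if self.laterality not in LATERALITIES:
            raise ValueError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )

    # -- derived physical quantities -------------------------------------

    @property
    def fov_um(self) -> float:
        """Lateral field-of-view extent in micrometres."""
        return self.fov_deg * self.mm_per_deg * 1000.0

    @property
    def lateral_spacing_um(self) -> float:
        """A-scan pitch: fov extent over ``n_ascans - 1`` intervals."""
        return self.fov_um / (self.n_ascans - 1)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_bscans, n_ascans) en-face array shape."""
        return (self.n_bscans, self.n_ascans)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {key: getattr(self, key) for key in _GEOMETRY_KEYS}

    @classmethod
    def from_dict(cls, data: dict) -> "ScanGeometry":
        missing = [k for k in _GEOMETRY_KEYS if k not in data]
        if missing:
            raise ValueError(f"geometry dict missing keys: {missing}")
        return cls(**{k: data[k] for k in _GEOMETRY_KEYS})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanGeometry":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"geometry sidecar not found: {path}")
        return cls.from_dict(json.loads(path.read_text()))


def make_geometry(
    fov_deg: float = 20.0,
    n_ascans: int = 1024,
    n_bscans: int = 49,
    mm_per_deg: float = 0.293,
    bscan_spacing_um: float | None = None,
    axial_pitch_um: float | None = None,
    laterality: str = "OD",
    device_label: str = "standard",
) -> ScanGeometry:
    """Build a validated :class:`ScanGeometry`.

    When ``bscan_spacing_um`` is omitted it is derived from the field of
    view: ``fov_deg * mm_per_deg * 1000 / (n_bscans - 1)``.
    """
    if bscan_spacing_um is None:
        if int(n_bscans) != n_bscans or n_bscans < 2:
            raise ValueError(f"n_bscans must be an integer >= 2, got {n_bscans!r}")
        _require_positive_finite("fov_deg", fov_deg)
        _require_positive_finite("mm_per_deg", mm_per_deg)
        bscan_spacing_um = fov_deg * mm_per_deg * 1000.0 / (n_bscans - 1)
    return ScanGeometry(
        n_ascans=n_ascans,
        n_bscans=n_bscans,
        fov_deg=fov_deg,
        mm_per_deg=mm_per_deg,
        bscan_spacing_um=bscan_spacing_um,
        axial_pitch_um=axial_pitch_um,
        laterality=laterality,
        device_label=device_label,
    )


def column_cell_area_um2(geometry: ScanGeometry) -> float:
    """En-face area represented by one A-scan column, in square micrometres."""
    return geometry.lateral_spacing_um * geometry.bscan_spacing_um


def column_cell_area_mm2(geometry: ScanGeometry) -> float:
    """En-face area represented by one A-scan column, in mm^2."""
    return column_cell_area_um2(geometry) / 1.0e6


def um3_to_nl(volume_um3: float) -> float:
    """Convert cubic micrometres to nanolitres (1 nL = 1e6 um^3)."""
    if volume_um3 < 0:
        raise ValueError(f"volume must be >= 0, got {volume_um3!r}")
    return volume_um3 / 1.0e6
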