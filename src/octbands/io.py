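"""Surface-table and map file formats.

A surface table is a TSV with one row per A-scan column per B-scan and
header columns exactly::

    eye_id  patient_id  device  bscan  ascan  elm_um  ez_inner_um
    ez_outer_um  rpe_inner_um  rpe_outer_um  sdd_disrupted

Empty cells encode missing surfaces (band loss).  A JSON sidecar
``<table>.geometry.json`` carries the :class:`~octbands.geometry.ScanGeometry`
plus the fovea center.  TSV over a binary format keeps fixtures
human-diffable and avoids proprietary OCT export parsing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ScanGeometry
from .surfaces import EnFaceMap, SurfaceSet

__all__ = [
    "SURFACE_TABLE_COLUMNS",
    "sidecar_path",
    "write_surface_table",
    "read_surface_table",
    "write_map_tsv",
    "read_map_tsv",
    "save_map_png",
]

SURFACE_TABLE_COLUMNS = (
    "eye_id", "patient_id", "device", "bscan", "ascan",
    "elm_um", "ez_inner_um", "ez_outer_um", "rpe_inner_um", "rpe_outer_um",
    "sdd_disrupted",
)

_SURFACE_TO_COLUMN = {
    "ELM": "elm_um",
    "EZ_inner": "ez_inner_um",
    "EZ_outer": "ez_outer_um",
    "RPE_inner": "rpe_inner_um",
    "RPE_outer": "rpe_outer_um",
}


def sidecar_path(table_path: str | Path) -> Path:
    return Path(str(table_path) + ".geometry.json")


def write_surface_table(surfaces: SurfaceSet, path: str | Path) -> Path:
    """Write a SurfaceSet as TSV plus its geometry sidecar.

    Floats are written at full precision so a read-back reproduces the
    arrays bit-identically.
    """
    path = Path(path)
    g = surfaces.geometry
    bb, aa = np.meshgrid(np.arange(g.n_bscans), np.arange(g.n_ascans),
                         indexing="ij")
    data = {
        "eye_id": surfaces.eye_id,
        "patient_id": surfaces.patient_id,
        "device": surfaces.device_label,
        "bscan": bb.ravel(),
        "ascan": aa.ravel(),
    }
    for name, col in _SURFACE_TO_COLUMN.items():
        data[col] = surfaces.surfaces[name].ravel()
    data["sdd_disrupted"] = surfaces.sdd_disrupted.ravel().astype(int)
    frame = pd.DataFrame(data, columns=list(SURFACE_TABLE_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")
    sidecar = {
        **g.to_dict(),
        "fovea_center": list(surfaces.fovea_center),
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_surface_table(path: str | Path) -> SurfaceSet:
    """Read and validate a surface table and its geometry sidecar.

    Errors name missing columns, lattice gaps or duplicates, and ordering
    violations (with row coordinates).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"surface table not found: {path}")
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"geometry sidecar not found: {side}")
    meta = json.loads(side.read_text())
    fovea = tuple(meta.pop("fovea_center"))
    geometry = ScanGeometry.from_dict(meta)

    frame = pd.read_csv(path, sep="\t", float_precision="round_trip",
                        dtype={"eye_id": str, "patient_id": str,
                               "device": str})
    if tuple(frame.columns) != SURFACE_TABLE_COLUMNS:
        raise ValueError(
            f"surface table header mismatch in {path}: expected "
            f"{list(SURFACE_TABLE_COLUMNS)}, got {list(frame.columns)}"
        )
    n_expected = geometry.n_bscans * geometry.n_ascans
    key = frame["bscan"].to_numpy() * geometry.n_ascans + frame["ascan"].to_numpy()
    if len(frame) != n_expected or len(np.unique(key)) != n_expected:
        raise ValueError(
            f"lattice coverage error in {path}: expected each of "
            f"{n_expected} columns exactly once, got {len(frame)} rows"
        )
    for col in _SURFACE_TO_COLUMN.values():
        vals = frame[col].to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValueError(f"non-finite value in column {col} of {path}")

    order = np.argsort(key, kind="stable")
    shape = geometry.shape
    surf_arrays = {
        name: frame[col].to_numpy(dtype=float)[order].reshape(shape)
        for name, col in _SURFACE_TO_COLUMN.items()
    }
    disrupted = (
        frame["sdd_disrupted"].to_numpy(dtype=int)[order].reshape(shape) != 0
    )
    surfaces = SurfaceSet(
        geometry=geometry,
        surfaces=surf_arrays,
        fovea_center=fovea,
        eye_id=str(frame["eye_id"].iloc[0]),
        patient_id=str(frame["patient_id"].iloc[0]),
        device_label=str(frame["device"].iloc[0]),
        sdd_disrupted=disrupted,
    )
    surfaces.validate()
    return surfaces


def write_map_tsv(enface: EnFaceMap, path: str | Path) -> Path:
    """Write an en-face map as a TSV matrix (missing = ``NA``)."""
    path = Path(path)
    pd.DataFrame(enface.values).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.17g",
        na_rep="NA",
    )
    return path


def read_map_tsv(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", header=None, na_values=["NA"],
                        float_precision="round_trip")
    return frame.to_numpy(dtype=float)


def save_map_png(enface: EnFaceMap, path: str | Path, cmap: str = "viridis",
                 title: str | None = None) -> Path:
    """Render an en-face map to PNG (documentation helper)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = enface.geometry
    extent = [0.0, g.fov_um / 1000.0,
              0.0, g.bscan_spacing_um * (g.n_bscans - 1) / 1000.0]
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(enface.values, origin="lower", cmap=cmap, extent=extent,
                   aspect="equal")
    fig.colorbar(im, ax=ax, label=enface.quantity_label)
    ax.set_xlabel("mm")
    ax.set_ylabel("mm")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
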