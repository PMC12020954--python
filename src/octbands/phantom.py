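"""Synthetic phantom eyes with known ground truth.

Generates paired two-device acquisitions of eyes with geographic atrophy at
the segmentation-surface level: smooth baseline surfaces for the five outer
retinal boundaries, an elliptical atrophy lesion with nested per-band
extents (EZ-loss extent contains ELM-loss extent contains RPE-loss extent by
default), drusen elevations, paraboloid subretinal drusenoid deposit (SDD)
mounds placed outside the central 1 mm with superior weighting, additive
device-specific band-thickness offsets, and per-column Gaussian jitter
projected back onto the anterior-to-posterior ordering constraint.

Ground truth (:class:`PhantomTruth`) is computed in closed form -- clipped
ellipse areas through polygon intersection and analytic paraboloid mound
volumes -- and never touches the quantification pipeline, so it can serve
as an independent reference for recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely.geometry as sgeom

from .geometry import ScanGeometry, make_geometry
from .surfaces import SURFACE_NAMES, SurfaceSet

__all__ = [
    "DeviceEffect",
    "LesionSpec",
    "DrusenSpec",
    "SddSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomEye",
    "Cohort",
    "generate_cohort",
    "worked_example_eye",
    "ellipse_area_mm2",
    "paraboloid_volume_nl",
    "paraboloid_visible_volume_nl",
]

BANDS = ("ELM_MZ", "EZ", "RPE")
QUADRANTS = ("superior", "nasal", "inferior", "temporal")

#: SDD thickness registration threshold in micrometres
SDD_THRESHOLD_UM = 4.0


@dataclass(frozen=True)
class DeviceEffect:
    """Additive per-band thickness offsets (um) and SDD visibility for one device.

    ``sdd_visibility`` scales the visible mound height: axial resolution
    limits how much of a shallow deposit a device registers, which is why
    higher-resolution devices report larger SDD volumes.
    """

    elm_mz_um: float = 0.0
    ez_um: float = 0.0
    rpe_um: float = 0.0
    sdd_visibility: float = 1.0


@dataclass(frozen=True)
class LesionSpec:
    """Elliptical atrophy lesion with nested per-band extents.

    The RPE-loss ellipse has the stated semi-axes; the ELM- and EZ-loss
    ellipses add their margins to both semi-axes, so by default the EZ-loss
    extent contains the ELM-loss extent contains the RPE-loss extent.
    Per-eye size variability is lognormal on a common scale factor,
    clamped to ``scale_range`` (loss areas are right-skewed, as in real
    atrophy cohorts).
    """

    center_offset_mm: tuple[float, float] = (0.4, 0.1)  # (x image-right, y superior)
    rpe_semi_axes_mm: tuple[float, float] = (1.0, 0.7)
    elm_margin_mm: float = 0.15
    ez_margin_mm: float = 0.30
    scale_sigma: float = 0.25
    scale_range: tuple[float, float] = (0.5, 1.6)
    center_jitter_mm: float = 0.15
    max_clip_fraction: float = 0.25


@dataclass(frozen=True)
class DrusenSpec:
    """Gaussian sub-RPE elevations lifting all five surfaces anteriorly.

    Drusen deform the surfaces without changing any band thickness or the
    EZ-RPE gap, matching their exclusion from band and SDD measurements.
    """

    count: int = 3
    height_mean_um: float = 40.0
    height_sd_um: float = 10.0
    sigma_mean_um: float = 300.0
    sigma_sd_um: float = 60.0
    max_radius_mm: float = 2.3


@dataclass(frozen=True)
class SddSpec:
    """Paraboloid SDD mounds between the EZ outer and RPE inner boundaries.

    Mound centers are drawn in an annulus excluding the central 1 mm, with
    anatomic-quadrant weights favouring the superior quadrant.  Mounds are
    rejection-sampled to stay inside the field of view, avoid each other,
    and avoid the EZ-loss lesion (where the gap would be unmeasurable).
    """

    count_mean: float = 30.0
    count_poisson: bool = True
    height_mean_um: float = 15.0
    height_sd_um: float = 3.0
    height_range_um: tuple[float, float] = (6.0, 18.0)
    radius_mean_um: float = 350.0
    radius_sd_um: float = 50.0
    radius_range_um: tuple[float, float] = (200.0, 500.0)
    radial_range_mm: tuple[float, float] = (0.85, 2.45)
    quadrant_weights: tuple[float, float, float, float] = (0.30, 0.23, 0.23, 0.24)
    disrupt_height_um: float | None = None


def _default_devices() -> dict[str, DeviceEffect]:
    # Offsets equal the cohort mean differences reported for a paired
    # standard-resolution vs high-resolution protocol: ELM+MZ -1.5 um,
    # EZ +1.1 um, RPE -5.1 um, with lower SDD visibility on the
    # standard-resolution device.
    return {
        "standard": DeviceEffect(0.0, 0.0, 0.0, sdd_visibility=0.65),
        "high_res": DeviceEffect(-1.5, +1.1, -5.1, sdd_visibility=1.0),
    }


@dataclass
class PhantomSpec:
    """Full description of a simulated cohort.

    Baseline band thicknesses (standard-resolution device) default to
    ELM+MZ 20 um, EZ 27 um, RPE 21 um -- the magnitude range reported for
    eyes with geographic atrophy -- with between-patient, between-eye and
    per-acquisition Gaussian variation.
    """

    seed: int = 0
    n_patients: int = 32
    prob_both_eyes: float = 0.25
    n_ascans: int = 1024
    n_bscans: int = 49
    fov_deg: float = 20.0
    mm_per_deg: float = 0.293
    elm_mz_um: float = 20.0
    ez_um: float = 27.0
    rpe_um: float = 21.0
    between_patient_sd_um: float = 1.5
    between_eye_sd_um: float = 1.5
    acquisition_sd_um: float = 0.8
    jitter_sd_um: float = 1.0
    lesion: LesionSpec | None = field(default_factory=LesionSpec)
    drusen: DrusenSpec = field(default_factory=DrusenSpec)
    sdd: SddSpec = field(default_factory=SddSpec)
    device_effects: dict[str, DeviceEffect] = field(default_factory=_default_devices)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.prob_both_eyes <= 1.0:
            raise ValueError("prob_both_eyes must be in [0, 1]")
        for name in ("between_patient_sd_um", "between_eye_sd_um",
                     "acquisition_sd_um", "jitter_sd_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.device_effects:
            raise ValueError("at least one device must be specified")
        if self.lesion is not None:
            a, b = self.lesion.rpe_semi_axes_mm
            if a < 0 or b < 0:
                raise ValueError("lesion semi-axes must be >= 0")


@dataclass
class PhantomTruth:
    """Analytic ground truth for one generated cohort.

    ``loss_areas``: per eye x device x band true loss area (mm^2) from
    clipped-ellipse geometry.  ``thickness``: per eye x device x band true
    (pre-jitter) mean band thickness (um).  ``sdd``: per eye x device x
    region true SDD volume, both the full geometric mound volume
    (``true_total_nl``, sum of 1/2*pi*r^2*h) and the closed-form volume
    above the 4 um registration threshold (``true_visible_nl``), which is
    what a thresholding measurement can recover.
    """

    loss_areas: pd.DataFrame
    thickness: pd.DataFrame
    sdd: pd.DataFrame
    lesions: pd.DataFrame
    mounds: pd.DataFrame


@dataclass
class PhantomEye:
    eye_id: str
    patient_id: str
    laterality: str
    acquisitions: dict[str, SurfaceSet]


@dataclass
class Cohort:
    eyes: list[PhantomEye]
    truth: PhantomTruth
    spec: PhantomSpec

    @property
    def n_eyes(self) -> int:
        return len(self.eyes)


# ---------------------------------------------------------------------------
# closed-form helpers (these deliberately avoid the quantification module)

def _ellipse_polygon(cx: float, cy: float, a: float, b: float,
                     n_vertices: int = 1440) -> sgeom.Polygon:
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return sgeom.Polygon(np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)]))


def ellipse_area_mm2(cx: float, cy: float, a: float, b: float,
                     rect: tuple[float, float, float, float] | None = None) -> float:
    """Area of an axis-aligned ellipse, optionally clipped to a rectangle.

    ``rect`` is (xmin, ymin, xmax, ymax) in mm.  Uses a fine polygonal
    approximation (relative error < 1e-5), independent of any lattice.
    """
    if a <= 0 or b <= 0:
        return 0.0
    if rect is None:
        return math.pi * a * b
    poly = _ellipse_polygon(cx, cy, a, b)
    return poly.intersection(sgeom.box(*rect)).area


def _union_area_mm2(ellipses: list[tuple[float, float, float, float]],
                    rect: tuple[float, float, float, float]) -> float:
    polys = [_ellipse_polygon(*e) for e in ellipses if e[2] > 0 and e[3] > 0]
    if not polys:
        return 0.0
    union = polys[0]
    for p in polys[1:]:
        union = union.union(p)
    return union.intersection(sgeom.box(*rect)).area


def paraboloid_volume_nl(radius_um: float, height_um: float) -> float:
    """Volume of a paraboloid cap h*(1 - d^2/r^2): V = 1/2 * pi * r^2 * h (nL)."""
    return 0.5 * math.pi * radius_um**2 * height_um / 1.0e6


def paraboloid_visible_volume_nl(radius_um: float, height_um: float,
                                 threshold_um: float = SDD_THRESHOLD_UM) -> float:
    """Integral of the paraboloid profile over the region where it exceeds
    ``threshold_um``: V * (1 - (t/h)^2); zero when the peak is below the
    threshold.  Closed form, used as the recoverable truth for thresholded
    SDD volumetry.
    """
    if height_um <= threshold_um:
        return 0.0
    return paraboloid_volume_nl(radius_um, height_um) * (
        1.0 - (threshold_um / height_um) ** 2
    )


def _quadrant_of(x_nasal: float, y_sup: float) -> str:
    ang = math.degrees(math.atan2(y_sup, x_nasal))
    if -45.0 <= ang < 45.0:
        return "nasal"
    if 45.0 <= ang < 135.0:
        return "superior"
    if -135.0 <= ang < -45.0:
        return "inferior"
    return "temporal"


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    return np.clip(out, lo, hi)


# ---------------------------------------------------------------------------

def generate_cohort(spec: PhantomSpec) -> Cohort:
    """Generate a reproducible cohort of paired multi-device phantom eyes.

    Identical ``spec`` (including ``spec.seed``) yields a bit-identical
    cohort.  Each eye is acquired on every device of
    ``spec.device_effects`` on an identical lattice with identical fovea
    center, emulating follow-up-registered paired imaging; only band
    offsets, SDD visibility, per-acquisition offsets and jitter differ
    between devices.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    devices = list(spec.device_effects)

    n_both = int(round(spec.prob_both_eyes * spec.n_patients))
    both = set(rng.choice(spec.n_patients, size=n_both, replace=False).tolist())

    fovea = (spec.n_bscans // 2, spec.n_ascans // 2)
    half_x = spec.fov_deg * spec.mm_per_deg / 2.0  # mm, lattice half-extent

    eyes: list[PhantomEye] = []
    loss_rows, thick_rows, sdd_rows, lesion_rows, mound_rows = [], [], [], [], []

    eye_counter = 0
    for p in range(spec.n_patients):
        patient_id = f"P{p:03d}"
        patient_eff = {band: rng.normal(0.0, spec.between_patient_sd_um)
                       for band in BANDS}
        n_eyes_patient = 2 if p in both else 1
        first_lat = "OD" if rng.random() < 0.5 else "OS"
        for e in range(n_eyes_patient):
            laterality = first_lat if e == 0 else ("OS" if first_lat == "OD" else "OD")
            eye_id = f"E{eye_counter:03d}"
            eye_counter += 1
            eye, rows = _generate_eye(
                spec, rng, devices, fovea, half_x,
                eye_id, patient_id, laterality, patient_eff,
            )
            eyes.append(eye)
            loss_rows += rows["loss"]
            thick_rows += rows["thickness"]
            sdd_rows += rows["sdd"]
            lesion_rows += rows["lesions"]
            mound_rows += rows["mounds"]

    truth = PhantomTruth(
        loss_areas=pd.DataFrame(
            loss_rows,
            columns=["eye_id", "patient_id", "device", "band", "true_loss_mm2"]),
        thickness=pd.DataFrame(
            thick_rows,
            columns=["eye_id", "patient_id", "device", "band", "true_mean_um"]),
        sdd=pd.DataFrame(
            sdd_rows,
            columns=["eye_id", "patient_id", "device", "region",
                     "true_total_nl", "true_visible_nl"]),
        lesions=pd.DataFrame(
            lesion_rows,
            columns=["eye_id", "band", "cx_mm", "cy_mm", "a_mm", "b_mm"]),
        mounds=pd.DataFrame(
            mound_rows,
            columns=["eye_id", "x_mm", "y_mm", "radius_um", "height_um",
                     "quadrant"]),
    )
    return Cohort(eyes=eyes, truth=truth, spec=spec)


def _generate_eye(spec, rng, devices, fovea, half_x,
                  eye_id, patient_id, laterality, patient_eff):
    b_f, a_f = fovea
    geometry0 = make_geometry(
        fov_deg=spec.fov_deg, n_ascans=spec.n_ascans, n_bscans=spec.n_bscans,
        mm_per_deg=spec.mm_per_deg, laterality=laterality)
    # image-frame column-center coordinates relative to the fovea (mm)
    x = (np.arange(spec.n_ascans) - a_f) * geometry0.lateral_spacing_um / 1000.0
    y = (np.arange(spec.n_bscans) - b_f) * geometry0.bscan_spacing_um / 1000.0
    X, Y = np.meshgrid(x, y)
    # continuous lattice extent: outermost column centers plus half a cell
    rect = (x[0] - geometry0.lateral_spacing_um / 2000.0,
            y[0] - geometry0.bscan_spacing_um / 2000.0,
            x[-1] + geometry0.lateral_spacing_um / 2000.0,
            y[-1] + geometry0.bscan_spacing_um / 2000.0)

    # per-eye band thicknesses (standard-device baseline)
    t_eye = {band: max(5.0, base + patient_eff[band]
                       + rng.normal(0.0, spec.between_eye_sd_um))
             for band, base in zip(BANDS, (spec.elm_mz_um, spec.ez_um, spec.rpe_um))}

    # smooth baseline ELM surface: depth offset, tilt, shallow bowl
    tilt = rng.normal(0.0, 5.0, size=2)      # um per mm
    bowl = abs(rng.normal(10.0, 3.0))        # um at the lattice corner
    rho2 = (X / half_x) ** 2 + (Y / half_x) ** 2
    base_elm = 250.0 + tilt[0] * X + tilt[1] * Y + bowl * rho2 / 2.0

    # drusen: anterior elevation of all five surfaces (no thickness change)
    if spec.drusen.count > 0:
        for _ in range(spec.drusen.count):
            rr = spec.drusen.max_radius_mm * math.sqrt(rng.random())
            th = rng.random() * 2.0 * math.pi
            cx, cy = rr * math.cos(th), rr * math.sin(th)
            h = max(0.0, rng.normal(spec.drusen.height_mean_um,
                                    spec.drusen.height_sd_um))
            sg = max(50.0, rng.normal(spec.drusen.sigma_mean_um,
                                      spec.drusen.sigma_sd_um)) / 1000.0  # mm
            base_elm -= h * np.exp(-(((X - cx) ** 2 + (Y - cy) ** 2)
                                     / (2.0 * sg**2)))

    # lesion ellipses (image frame, mm)
    lesion_rows = []
    ellipses: dict[str, tuple[float, float, float, float]] = {}
    if spec.lesion is not None and max(spec.lesion.rpe_semi_axes_mm) > 0:
        les = spec.lesion
        scale = float(np.clip(math.exp(rng.normal(0.0, les.scale_sigma)),
                              *les.scale_range))
        cx = les.center_offset_mm[0] + rng.normal(0.0, les.center_jitter_mm)
        cy = les.center_offset_mm[1] + rng.normal(0.0, les.center_jitter_mm)
        a_rpe, b_rpe = (les.rpe_semi_axes_mm[0] * scale,
                        les.rpe_semi_axes_mm[1] * scale)
        ellipses = {
            "RPE_lesion": (cx, cy, a_rpe, b_rpe),
            "ELM_lesion": (cx, cy, a_rpe + les.elm_margin_mm,
                           b_rpe + les.elm_margin_mm),
            "EZ_lesion": (cx, cy, a_rpe + les.ez_margin_mm,
                          b_rpe + les.ez_margin_mm),
        }
        ez_full = math.pi * ellipses["EZ_lesion"][2] * ellipses["EZ_lesion"][3]
        ez_clip = ellipse_area_mm2(*ellipses["EZ_lesion"], rect=rect)
        if ez_full > 0 and 1.0 - ez_clip / ez_full > les.max_clip_fraction:
            raise ValueError(
                f"lesion of eye {eye_id} exceeds the field of view by more "
                f"than the clip policy ({les.max_clip_fraction:.0%}): "
                f"clipped fraction {1.0 - ez_clip / ez_full:.1%}")
        for name, ell in ellipses.items():
            lesion_rows.append([eye_id, name, *ell])

    def inside(ell):
        cx, cy, a, b = ell
        if a <= 0 or b <= 0:
            return np.zeros_like(X, dtype=bool)
        return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0

    elm_lost = inside(ellipses["ELM_lesion"]) if ellipses else np.zeros_like(X, bool)
    ez_lost = inside(ellipses["EZ_lesion"]) if ellipses else np.zeros_like(X, bool)
    rpe_lost = inside(ellipses["RPE_lesion"]) if ellipses else np.zeros_like(X, bool)

    # SDD mounds (anatomic frame for placement; image frame for rasterization)
    mounds = _place_mounds(spec, rng, half_x, laterality,
                           ellipses.get("EZ_lesion"))
    mound_rows = [[eye_id, m["x_img"], m["y"], m["r_um"], m["h_um"], m["quad"]]
                  for m in mounds]

    gap_unit = np.zeros_like(X)  # summed mound profile at visibility 1
    for m in mounds:
        r_mm = m["r_um"] / 1000.0
        ia = np.searchsorted(x, [m["x_img"] - r_mm, m["x_img"] + r_mm])
        ib = np.searchsorted(y, [m["y"] - r_mm, m["y"] + r_mm])
        sl = (slice(max(ib[0] - 1, 0), ib[1] + 1),
              slice(max(ia[0] - 1, 0), ia[1] + 1))
        d2 = ((X[sl] - m["x_img"]) ** 2 + (Y[sl] - m["y"]) ** 2) / r_mm**2
        prof = m["h_um"] * np.maximum(0.0, 1.0 - d2)
        gap_unit[sl] += prof

    rows = {"loss": [], "thickness": [], "sdd": [],
            "lesions": lesion_rows, "mounds": mound_rows}
    acquisitions: dict[str, SurfaceSet] = {}
    for dev in devices:
        eff = spec.device_effects[dev]
        t_dev = {
            "ELM_MZ": max(3.0, t_eye["ELM_MZ"] + eff.elm_mz_um
                          + rng.normal(0.0, spec.acquisition_sd_um)),
            "EZ": max(3.0, t_eye["EZ"] + eff.ez_um
                      + rng.normal(0.0, spec.acquisition_sd_um)),
            "RPE": max(3.0, t_eye["RPE"] + eff.rpe_um
                       + rng.normal(0.0, spec.acquisition_sd_um)),
        }
        gap = gap_unit * eff.sdd_visibility
        elm = base_elm.copy()
        ez_inner = elm + t_dev["ELM_MZ"]
        rpe_inner = ez_inner + t_dev["EZ"]
        rpe_outer = rpe_inner + t_dev["RPE"]
        ez_outer = rpe_inner - gap

        surfaces = {"ELM": elm, "EZ_inner": ez_inner, "EZ_outer": ez_outer,
                    "RPE_inner": rpe_inner, "RPE_outer": rpe_outer}
        if spec.jitter_sd_um > 0:
            for name in SURFACE_NAMES:
                surfaces[name] = surfaces[name] + rng.normal(
                    0.0, spec.jitter_sd_um, size=surfaces[name].shape)
        # ordering projection: a posterior surface crossed by its anterior
        # neighbour is raised onto it
        for prev, cur in zip(SURFACE_NAMES[:-1], SURFACE_NAMES[1:]):
            surfaces[cur] = np.maximum(surfaces[cur], surfaces[prev])

        surfaces["ELM"][elm_lost] = np.nan
        surfaces["EZ_inner"][ez_lost] = np.nan
        surfaces["EZ_outer"][ez_lost] = np.nan
        surfaces["RPE_inner"][rpe_lost] = np.nan
        surfaces["RPE_outer"][rpe_lost] = np.nan

        disrupted = np.zeros_like(X, dtype=bool)
        disrupt_h = spec.sdd.disrupt_height_um
        if disrupt_h is not None:
            disrupted = gap > disrupt_h

        geometry = dataclasses.replace(geometry0, device_label=dev)
        acquisitions[dev] = SurfaceSet(
            geometry=geometry, surfaces=surfaces, fovea_center=(b_f, a_f),
            eye_id=eye_id, patient_id=patient_id, device_label=dev,
            sdd_disrupted=disrupted)

        # ---- analytic truth for this acquisition ----
        band_loss = {
            "ELM_MZ": _union_area_mm2(
                [ellipses[k] for k in ("ELM_lesion", "EZ_lesion")
                 if k in ellipses], rect),
            "EZ": _union_area_mm2(
                [ellipses[k] for k in ("EZ_lesion", "RPE_lesion")
                 if k in ellipses], rect),
            "RPE": _union_area_mm2(
                [ellipses[k] for k in ("RPE_lesion",) if k in ellipses], rect),
        }
        if disrupt_h is not None:
            # closed form: paraboloid profile exceeds d on a disc of area
            # pi r^2 (1 - d/h); mounds never overlap the lesion or each other
            extra = sum(
                math.pi * (m["r_um"] / 1000.0) ** 2
                * (1.0 - disrupt_h / (m["h_um"] * eff.sdd_visibility))
                for m in mounds if m["h_um"] * eff.sdd_visibility > disrupt_h)
            band_loss["EZ"] += extra
        for band in BANDS:
            rows["loss"].append([eye_id, patient_id, dev, band, band_loss[band]])
            rows["thickness"].append([eye_id, patient_id, dev, band, t_dev[band]])

        per_quad = {q: [0.0, 0.0] for q in QUADRANTS}
        total = [0.0, 0.0]
        for m in mounds:
            h_vis = m["h_um"] * eff.sdd_visibility
            v_tot = paraboloid_volume_nl(m["r_um"], h_vis)
            v_vis = paraboloid_visible_volume_nl(m["r_um"], h_vis)
            per_quad[m["quad"]][0] += v_tot
            per_quad[m["quad"]][1] += v_vis
            total[0] += v_tot
            total[1] += v_vis
        rows["sdd"].append([eye_id, patient_id, dev, "whole_field", *total])
        for q in QUADRANTS:
            rows["sdd"].append([eye_id, patient_id, dev, q, *per_quad[q]])

    eye = PhantomEye(eye_id=eye_id, patient_id=patient_id,
                     laterality=laterality, acquisitions=acquisitions)
    return eye, rows


def _place_mounds(spec, rng, half_x, laterality, ez_lesion):
    sdd = spec.sdd
    if sdd.count_mean <= 0:
        return []
    n = (int(rng.poisson(sdd.count_mean)) if sdd.count_poisson
         else int(round(sdd.count_mean)))
    weights = np.asarray(sdd.quadrant_weights, dtype=float)
    weights = weights / weights.sum()
    quad_angle = {"nasal": 0.0, "superior": 90.0, "inferior": -90.0,
                  "temporal": 180.0}
    mounds = []
    for _ in range(n):
        for _try in range(300):
            quad = QUADRANTS[rng.choice(4, p=weights)]
            ang = math.radians(quad_angle[quad] + rng.uniform(-45.0, 45.0))
            r_pos = rng.uniform(*sdd.radial_range_mm)
            x_nasal = r_pos * math.cos(ang)
            y_sup = r_pos * math.sin(ang)
            x_img = x_nasal if laterality == "OD" else -x_nasal
            r_um = float(_truncnorm(rng, sdd.radius_mean_um, sdd.radius_sd_um,
                                    *sdd.radius_range_um, size=1)[0])
            h_um = float(_truncnorm(rng, sdd.height_mean_um, sdd.height_sd_um,
                                    *sdd.height_range_um, size=1)[0])
            r_mm = r_um / 1000.0
            if abs(x_img) + r_mm > half_x - 0.02 or abs(y_sup) + r_mm > half_x - 0.02:
                continue
            if ez_lesion is not None:
                cx, cy, a, b = ez_lesion
                if (((x_img - cx) / (a + r_mm)) ** 2
                        + ((y_sup - cy) / (b + r_mm)) ** 2) < 1.0:
                    continue
            if any((m["x_img"] - x_img) ** 2 + (m["y"] - y_sup) ** 2
                   < (m["r_um"] / 1000.0 + r_mm) ** 2 for m in mounds):
                continue
            mounds.append({"x_img": x_img, "y": y_sup, "r_um": r_um,
                           "h_um": h_um, "quad": quad})
            break
    return mounds


def worked_example_eye() -> tuple[PhantomEye, PhantomTruth]:
    """Deterministic miniature phantom eye (64 A-scans x 9 B-scans).

    One lesion and three SDD mounds, acquired on both default devices.
    Repeated calls are bit-identical (fixed internal seed).
    """
    spec = PhantomSpec(
        seed=7,
        n_patients=1,
        prob_both_eyes=0.0,
        n_ascans=64,
        n_bscans=9,
        lesion=LesionSpec(center_offset_mm=(0.3, 0.0),
                          rpe_semi_axes_mm=(0.8, 0.5),
                          scale_sigma=0.0, center_jitter_mm=0.0),
        drusen=DrusenSpec(count=1),
        sdd=SddSpec(count_mean=3, count_poisson=False),
    )
    cohort = generate_cohort(spec)
    return cohort.eyes[0], cohort.truth
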