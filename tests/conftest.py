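import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from octbands.geometry import make_geometry
from octbands.phantom import (
    DeviceEffect,
    DrusenSpec,
    LesionSpec,
    PhantomSpec,
    SddSpec,
    generate_cohort,
    worked_example_eye,
)
from octbands.surfaces import SURFACE_NAMES, SurfaceSet


@pytest.fixture(scope="session")
def default_geometry():
    return make_geometry()


@pytest.fixture(scope="session")
def small_geometry():
    """64 x 9 lattice sharing the 20-degree field of view."""
    return make_geometry(n_ascans=64, n_bscans=9)


def flat_surface_set(geometry, levels=None, fovea=None, **kwargs):
    """SurfaceSet with spatially constant surfaces at the given depths (um)."""
    if levels is None:
        levels = {"ELM": 250.0, "EZ_inner": 270.0, "EZ_outer": 297.0,
                  "RPE_inner": 297.0, "RPE_outer": 318.0}
    if fovea is None:
        fovea = (geometry.n_bscans // 2, geometry.n_ascans // 2)
    surfaces = {name: np.full(geometry.shape, levels[name], dtype=float)
                for name in SURFACE_NAMES}
    return SurfaceSet(geometry=geometry, surfaces=surfaces,
                      fovea_center=fovea, **kwargs)


@pytest.fixture()
def flat_eye(small_geometry):
    return flat_surface_set(small_geometry)


@pytest.fixture(scope="session")
def worked_example():
    """Deterministic miniature phantom eye with truth tables."""
    return worked_example_eye()


@pytest.fixture(scope="session")
def lesion_only_cohort():
    """One default-lattice eye with a lesion and nothing else."""
    spec = PhantomSpec(
        seed=11, n_patients=1, prob_both_eyes=0.0,
        lesion=LesionSpec(rpe_semi_axes_mm=(1.0, 0.7), scale_sigma=0.0),
        drusen=DrusenSpec(count=0), sdd=SddSpec(count_mean=0),
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def sdd_only_cohort():
    """One default-lattice eye with SDD mounds and no lesion or drusen."""
    spec = PhantomSpec(
        seed=13, n_patients=1, prob_both_eyes=0.0,
        lesion=None, drusen=DrusenSpec(count=0),
        sdd=SddSpec(count_mean=20, count_poisson=False),
    )
    return generate_cohort(spec)


def reduced_stats_spec(seed, effect_um=-5.1, n_patients=20):
    """Small, fast cohort for inference simulations: 128 x 13 lattice,
    paired devices differing only by an RPE thickness offset."""
    return PhantomSpec(
        seed=seed, n_patients=n_patients, prob_both_eyes=0.25,
        n_ascans=128, n_bscans=13,
        lesion=None, drusen=DrusenSpec(count=0), sdd=SddSpec(count_mean=0),
        device_effects={
            "standard": DeviceEffect(),
            "high_res": DeviceEffect(rpe_um=effect_um),
        },
    )
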