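import numpy as np
import pytest

from psmbio.cohort_sim import default_params, simulate_cohort
from psmbio.phantom import PhantomSpec, StructureSpec, render_phantom


def make_phantom_spec(
    ff: float = 0.10,
    enhancement: tuple = (0.10, 0.22, 0.25),
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    seed: int = 1,
    shape: tuple = (96, 96),
    spacing: tuple = (1.0, 1.0),
    total_density: float = 100.0,
) -> PhantomSpec:
    """Two PSMs with the given fat fraction and enhancement, plus aorta and
    a faint background."""
    fat = total_density * ff
    water = total_density - fat
    return PhantomSpec(
        shape=shape,
        spacing_mm=spacing,
        structures=[
            StructureSpec(
                label="background", center_mm=(0, 0), semi_axes_mm=(1, 1),
                water_density=5, fat_density=0, s0=10.0,
            ),
            StructureSpec(
                label="psm_left", center_mm=(60, 25), semi_axes_mm=(14, 9),
                water_density=water, fat_density=fat, s0=200.0,
                enhancement=enhancement,
            ),
            StructureSpec(
                label="psm_right", center_mm=(60, 70), semi_axes_mm=(14, 9),
                water_density=water, fat_density=fat, s0=200.0,
                enhancement=enhancement,
            ),
            StructureSpec(
                label="aorta", center_mm=(20, 48), semi_axes_mm=(6, 6),
                water_density=100, fat_density=0, s0=300.0,
                enhancement=(1.5, 0.8, 0.5),
            ),
        ],
        noise_sd=noise_sd,
        noise_model=noise_model,
        seed=seed,
    )


@pytest.fixture
def phantom_spec():
    return make_phantom_spec()


@pytest.fixture
def rendered_phantom(phantom_spec):
    return render_phantom(phantom_spec)


@pytest.fixture(scope="session")
def reference_cohort():
    """One 224-patient synthetic datasheet under the default conditions."""
    return simulate_cohort(default_params(n=224, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240822)
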