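import numpy as np
import pytest

from gafunc.enface import EnFaceMap, Feature, Laterality
from gafunc.pipeline import reduce_volumes, standardize_cohort
from gafunc.synth import SynthConfig, generate_cohort


def random_enface(
    rng: np.ndarray,
    feature: Feature = Feature.RPE_LOSS,
    shape=(49, 49),
    field_mm: float = 6.0,
    laterality: Laterality = Laterality.OD,
    fovea=None,
) -> EnFaceMap:
    """A random but spatially smooth en-face probability map."""
    from scipy.ndimage import gaussian_filter

    g = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    g = (g - g.min()) / max(float(np.ptp(g)), 1e-12)
    spacing = (field_mm / shape[0], field_mm / shape[1])
    return EnFaceMap(
        feature=feature,
        grid=g,
        spacing_mm=spacing,
        fovea_xy_mm=fovea or (field_mm / 2, field_mm / 2),
        laterality=laterality,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient synthetic cohort shared across tests."""
    return generate_cohort(SynthConfig(n_patients=30, rng_seed=3))


@pytest.fixture(scope="session")
def small_cohort_grids(small_cohort):
    maps, _ = reduce_volumes(small_cohort.volumes)
    return standardize_cohort(maps)
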