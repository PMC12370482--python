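import numpy as np
import pytest

from laserlesion.synthetic import (
    BeamProfile,
    LesionPhenotypeParams,
    simulate_thermal_video,
    simulate_viability_image,
    thermal_params_from_anchors,
)

#: printed anchor pairs of the irradiance→temperature standard curve
ANCHORS = [(7.3, 44.5), (12.22, 50.0)]
AMBIENT = 34.5


@pytest.fixture(scope="session")
def anchor_thermal():
    """Thermal params whose line passes exactly through the two anchors."""
    return thermal_params_from_anchors(ANCHORS, ambient=AMBIENT)


@pytest.fixture(scope="session")
def pt_beam():
    return BeamProfile(diameter=726.0, irradiance=12.22, wavelength=2000.0)


@pytest.fixture(scope="session")
def pc_beam():
    return BeamProfile(diameter=825.0, irradiance=8.84, wavelength=447.0)


@pytest.fixture(scope="session")
def pt_phenotype():
    return LesionPhenotypeParams(kind="photothermal", T_crit=44.0)


@pytest.fixture(scope="session")
def pt_image(pt_beam, anchor_thermal, pt_phenotype):
    """One cached photothermal lesion image + ground truth."""
    return simulate_viability_image(
        pt_beam, anchor_thermal, pt_phenotype, seed=7, shape=(320, 320),
        pixel_pitch=3.0,
    )


@pytest.fixture(scope="session")
def pt_video(pt_beam, anchor_thermal):
    """Thermal stack sharing ground truth with pt_image."""
    return simulate_thermal_video(
        pt_beam, anchor_thermal, fps=50.0, seed=70, frame_shape=(176, 176),
        duration=3.0,
    )


@pytest.fixture(scope="session")
def pc_image(pc_beam, anchor_thermal):
    pheno = LesionPhenotypeParams(kind="photochemical", p_death_max=0.5)
    return simulate_viability_image(
        pc_beam, anchor_thermal, pheno, seed=11, shape=(320, 320),
        pixel_pitch=3.0,
    )


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
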