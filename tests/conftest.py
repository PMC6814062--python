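import numpy as np
import pytest

from osteotherm import acoustics as ac
from osteotherm import sources as src
from osteotherm import thermal as th
from osteotherm.geometry import (GeometryParams, build_tissue_map,
                                 inner_cortical_facet)

# coarse surface elements keep the Rayleigh integral fast in tests;
# accuracy vs the closed form is still ~0.5% (checked in test_acoustics)
FAST_ELEMENT_MM = 1.5


@pytest.fixture(scope="session")
def geom_1mm() -> GeometryParams:
    return GeometryParams(grid_spacing_mm=1.0)


@pytest.fixture(scope="session")
def tmap_1mm(geom_1mm):
    return build_tissue_map(geom_1mm)


@pytest.fixture(scope="session")
def medium() -> ac.MediumSpec:
    return ac.MediumSpec()


@pytest.fixture(scope="session")
def transducer() -> ac.TransducerSpec:
    return ac.TransducerSpec(efficiency=0.228)


@pytest.fixture(scope="session")
def pressure_1mm(transducer, medium, tmap_1mm):
    with np.errstate(all="ignore"):
        return ac.rayleigh_pressure(transducer, medium, tmap_1mm,
                                    element_size_mm=FAST_ELEMENT_MM)


@pytest.fixture(scope="session")
def intensity_1mm(pressure_1mm, medium):
    return ac.intensity_from_pressure(pressure_1mm, medium)


@pytest.fixture(scope="session")
def facet_1mm(tmap_1mm, transducer):
    focus = tmap_1mm.breakthrough_center_mm
    return inner_cortical_facet(tmap_1mm, transducer.beam_spec(focus))


@pytest.fixture(scope="session")
def source_params() -> src.SourceParams:
    return src.SourceParams()


@pytest.fixture(scope="session")
def thermal_params() -> th.ThermalParams:
    return th.ThermalParams()
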