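import numpy as np
import pytest

from nirsox import (CohortSpec, ExtinctionTable, PathlengthSpec, ProbeGeometry,
                    default_tissue_model, run_study, simulate)
from nirsox.tissue_mc import OpticalLayer, TissueModel


@pytest.fixture(scope="session")
def eps() -> ExtinctionTable:
    return ExtinctionTable.default()


@pytest.fixture(scope="session")
def path() -> PathlengthSpec:
    return PathlengthSpec()


@pytest.fixture(scope="session")
def calf_model() -> TissueModel:
    return default_tissue_model()


@pytest.fixture(scope="session")
def diffusive_medium() -> TissueModel:
    """Matched-boundary semi-infinite medium in the diffusion regime
    (mu_a = 0.01, mu_s' = 1.0 mm^-1, isotropic scattering)."""
    return TissueModel(
        layers=(OpticalLayer(mu_a=0.01, mu_s=1.0, g=0.0, n=1.0, thickness_mm=None),),
        n_ambient=1.0)


@pytest.fixture(scope="session")
def calf_scan_summary(calf_model):
    """One shared calf-model run scoring apertures at 1/2/2/3 cm."""
    geometry = ProbeGeometry(detector_separations_cm=(1.0, 2.0, 2.0, 3.0))
    return simulate(calf_model, geometry, n_photons=100_000,
                    wavelength=805.0, seed=7)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (6+6 subjects, master seed 42) processed
    end to end: (cohort, processed triples, CohortResult)."""
    return run_study(CohortSpec(seed=42))
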