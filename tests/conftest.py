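import numpy as np
import pytest

from cdk9pkpd import ConcentrationProfile, DoseEvent, OneCompartmentParams, concentration_at


@pytest.fixture
def clinical_dose() -> DoseEvent:
    """The study regimen: 30 mg over a 0.5-h IV infusion."""
    return DoseEvent(dose_mg=30.0, infusion_h=0.5)


@pytest.fixture
def reference_params() -> OneCompartmentParams:
    return OneCompartmentParams(clearance=10.0, volume=50.0)


@pytest.fixture
def rich_profile(reference_params, clinical_dose) -> ConcentrationProfile:
    """Noise-free analytic profile with dense sampling over 0–48 h."""
    times = np.concatenate([[0.0], np.geomspace(0.05, 48.0, 300)])
    conc = concentration_at(reference_params, clinical_dose, times)
    return ConcentrationProfile("ref", clinical_dose, times, conc)
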