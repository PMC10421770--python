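import numpy as np
import pytest

from tafpk import DosingRegimen, ImplantInput, IVInfusion, PKParameters


@pytest.fixture
def systemic_params():
    """Published systemic parameter estimates for TFV in beagle dogs."""
    return PKParameters(V=84.7, Cl=174.0, Vp=534.0, Clp=681.0,
                        MAT=1.0 / 1440.0, F=3.4, Kout=1.84, vmkm=1.7e-4,
                        sigma_plasma=0.746, sigma_pbmc=1.05)


@pytest.fixture
def implant_regimen():
    """Single high-releasing implant, placed day 0 and removed day 30."""
    return DosingRegimen(
        events=[ImplantInput(rate=2.1, start=0.0, stop=30.0)],
        body_weight=10.5)


@pytest.fixture
def iv_regimen():
    """1.0 mg/kg TAF infused over 30 minutes into a 10.5 kg dog."""
    return DosingRegimen(
        events=[IVInfusion(dose=10.5, duration=30.0 / 1440.0, start=0.0)],
        body_weight=10.5)


@pytest.fixture
def random_param_sets():
    """A handful of physiologically plausible random parameter sets."""
    rng = np.random.default_rng(20240917)
    sets = []
    for _ in range(3):
        v = rng.uniform(20, 200)
        sets.append(PKParameters(
            V=v,
            Cl=rng.uniform(0.5, 3.0) * v,
            Vp=rng.uniform(2, 8) * v,
            Clp=rng.uniform(1, 6) * v,
            MAT=rng.uniform(1e-4, 0.05),
            F=rng.uniform(0.5, 12.0),
            Kout=rng.uniform(0.5, 4.0),
            vmkm=rng.uniform(0.1, 3.0),
        ))
    return sets
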