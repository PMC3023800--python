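import numpy as np
import pytest

import stabfit as sf


@pytest.fixture
def eq_truth():
    """Equilibrium titration parameters with sloping baselines."""
    return sf.TwoStateEqParams(
        dg_h2o=30.0, m_value=10.0, temperature=293.15,
        bn0=1.0, bu0=-10.0, an=0.1, au=-0.2,
    )


@pytest.fixture
def eq_curve(eq_truth):
    """15-point noiseless titration spanning both baselines."""
    d = np.linspace(0.0, 6.0, 15)
    return d, sf.equilibrium_signal(eq_truth, d)


@pytest.fixture
def wt_stability():
    """Anchored stability curve of the hyperthermostable wild type."""
    return sf.StabilityCurveParams.anchored_at(dh_tm=890.0, dcp=12.8, tm=375.15)


@pytest.fixture
def melt_truth():
    """Thermal melt with midpoint at 49.1 C and sloping baselines."""
    return sf.ThermalMeltParams(tm=49.1 + 273.15, dhm=400.0,
                                bn=0.0, bu=-10.0, an=0.05, au=-0.1)


@pytest.fixture
def kinetic_truth():
    return sf.KineticParams(k_app=0.01, amplitude=-5.0, a_inf=-10.0)
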