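import numpy as np
import pytest

from iminegel import kinetics
from iminegel.spectro import ConcentrationTrace

# study conditions used throughout: oxime formation on oxidized alginate
# (the 2+5 pair), 0.5 mM equimolar, 30 s sampling over 2 h
K1_25 = 0.058  # L/mol/s
KM1_25 = 5.2e-5  # 1/s
X0_25 = 5e-4  # mol/L
EPS_25 = 950.0  # L/mol/cm
SAMPLING = np.arange(0.0, 7201.0, 30.0)  # s


@pytest.fixture(scope="session")
def amine_trace_25():
    """Noiseless amine-consumption trace at the oxime study conditions."""
    x = kinetics.reversible_equimolar_solution(SAMPLING, K1_25, KM1_25, X0_25)
    return ConcentrationTrace(times=SAMPLING, concentration=x,
                              species="amine", x0=X0_25)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
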