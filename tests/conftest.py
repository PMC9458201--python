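import math

import numpy as np
import pytest
from scipy.integrate import quad

from cdbind.constants import KB, STANDARD_VOLUME


def boresch_quadrature_oracle(restraint, temperature=298.0, standard_volume=STANDARD_VOLUME):
    """Independent 6-D numerical evaluation of the restrained configuration
    integral (separable 1-D quadratures with the r^2 sin(thetaA) sin(thetaB)
    Jacobian), returning kT ln(8 pi^2 V0 / Z)."""
    kt = KB * temperature
    b = 1.0 / kt

    r0, kr = restraint.r0, restraint.k_r
    r_hi = r0 + 20.0 * math.sqrt(kt / kr)
    z_r = quad(lambda r: r**2 * np.exp(-b * kr * (r - r0) ** 2 / 2), 0.0, r_hi)[0]

    def z_theta(theta0_deg, k):
        t0 = math.radians(theta0_deg)
        return quad(lambda t: np.sin(t) * np.exp(-b * k * (t - t0) ** 2 / 2), 0.0, math.pi)[0]

    def z_phi(k):
        return quad(lambda p: np.exp(-b * k * p**2 / 2), -math.pi, math.pi)[0]

    z = (
        z_r
        * z_theta(restraint.thetaA0, restraint.k_thetaA)
        * z_theta(restraint.thetaB0, restraint.k_thetaB)
        * z_phi(restraint.k_phiA)
        * z_phi(restraint.k_phiB)
        * z_phi(restraint.k_phiC)
    )
    return kt * math.log(8.0 * math.pi**2 * standard_volume / z)


@pytest.fixture
def paper_conc_design():
    """Host concentration series in M: 0 then 0.1-4.0 mM."""
    return (
        np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 2.0, 3.0, 4.0])
        * 1e-3
    )
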