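"""Physical constants and unit conventions.

Internal unit system (matches the force constants as printed in the
molecular-mechanics literature): nm for distances, kJ/mol for energies,
ps for times, amu for masses, K for temperatures.  Spectroscopic
quantities keep their native units: ppm for chemical shifts, Hz for
frequency offsets, µM for concentrations, s for relaxation delays.
All conversions happen at module boundaries, never inside the math.
"""

import numpy as np

#: Boltzmann constant, kJ/(mol K)  (gas constant R in MD units)
KB_KJ_PER_MOL_K = 0.008314462618

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8

#: reduced Planck constant, J s
HBAR = 1.054571817e-34

#: mu_0 / 4 pi, T m A^-1
MU0_OVER_4PI = 1.0e-7

#: ideal methyl geometry H-H distance, nm
R_HH_METHYL_NM = 0.1813


def methyl_tq_prefactor(r_hh_nm: float = R_HH_METHYL_NM) -> float:
    """Dipolar prefactor linking the intra-methyl 1H-1H cross-correlated
    relaxation rate eta (s^-1) to the product S2*tauC (s):

        eta = (9/10) (mu0/4pi)^2 gammaH^4 hbar^2 / r_HH^6 * S2_tauC

    Returns the prefactor in s^-2 for ``r_hh_nm`` in nanometres.
    """
    r_m = r_hh_nm * 1e-9
    return 0.9 * MU0_OVER_4PI**2 * GAMMA_H**4 * HBAR**2 / r_m**6


def ppm_to_hz(ppm: float | np.ndarray, spectrometer_freq_mhz: float):
    """Convert a shift difference in ppm to Hz at the observed-nucleus
    Larmor frequency given in MHz. Never inferred: always explicit."""
    return np.asarray(ppm) * spectrometer_freq_mhz


def hz_to_ppm(hz: float | np.ndarray, spectrometer_freq_mhz: float):
    if spectrometer_freq_mhz <= 0:
        raise ValueError("spectrometer frequency must be positive")
    return np.asarray(hz) / spectrometer_freq_mhz
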