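"""Physical constants and shared defaults.

Energies are in kcal/mol throughout, distances in Angstrom, angles in
degrees at API boundaries (converted to radians internally where the
mathematics requires it).
"""

#: Boltzmann constant, kcal/(mol K).
KB = 1.987204e-3

#: Default simulation/experiment temperature, K.
DEFAULT_TEMPERATURE = 298.0

#: Standard-state volume corresponding to a 1 mol/L concentration, A^3.
STANDARD_VOLUME = 1660.539

#: 1H gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_1H = 2.6752218744e8

#: Conversion factor from gauss/cm to T/m.
GAUSS_PER_CM_TO_T_PER_M = 1e-2

#: Default gradient pulse duration (delta), s.  Not a measured value:
#: acquisition constants of the diffusion experiment are free parameters
#: of the generator and must accompany any series to be fitted.
DEFAULT_LITTLE_DELTA = 2e-3

#: Default diffusion delay (Delta), s.  Same caveat as above.
DEFAULT_BIG_DELTA = 100e-3


def beta(temperature: float) -> float:
    """Inverse temperature 1/(kB*T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)
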