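"""Physical constants and unit conversions.

Internal units are Å for length, ns for time, elementary charges for
charge, mV for voltage, K for temperature. Conversions to SI happen only
at the boundaries defined here.
"""

BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: Current conversion: 1 e/ns = 1.602176634e-19 C / 1e-9 s = 1.602e-10 A.
PA_PER_E_NS = ELEMENTARY_CHARGE_C / 1e-9 * 1e12  # = 160.2176634 pA per e/ns

#: Default simulation temperature (K) for constant-voltage ion transport runs.
DEFAULT_TEMPERATURE_K = 333.0


def kT_joule(temperature_K: float) -> float:
    """Thermal energy k_B·T in joules."""
    return BOLTZMANN_J_PER_K * temperature_K


def beta_e_per_mV(temperature_K: float) -> float:
    """e/(k_B·T) expressed per millivolt: the factor multiplying q·V_mV to
    obtain energy in units of k_B·T."""
    return ELEMENTARY_CHARGE_C * 1e-3 / kT_joule(temperature_K)
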