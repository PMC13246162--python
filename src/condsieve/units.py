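"""Internal unit system and physical constants.

Lengths are in nm, times in ns, masses in ag (1 ag = 1e-21 kg) and energies
in units of kB*T at the configured temperature ("kBT units").  With these
choices 1 ag*nm^2/ns^2 = 1e-21 J, so the kBT energy unit has a simple
numeric value in mechanical units and SI conversions are confined to the
pressure/temperature interfaces.
"""

KB = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
T_REF = 300.0  # K, default simulation temperature
WATER_VISCOSITY = 0.001  # kg/(m s); documents Stokes-Einstein D only


def kbt_joules(temperature: float = T_REF) -> float:
    """kB*T in joules."""
    return KB * temperature


def kbt_mech(temperature: float = T_REF) -> float:
    """kB*T expressed in ag*nm^2/ns^2 (= 1e-21 J)."""
    return kbt_joules(temperature) / 1e-21


def pa_per_kbt_nm3(temperature: float = T_REF) -> float:
    """Conversion factor: 1 kBT/nm^3 in pascals."""
    return kbt_joules(temperature) / 1e-27


def stokes_einstein_diffusivity(radius_nm: float, temperature: float = T_REF) -> float:
    """Stokes-Einstein diffusion coefficient in nm^2/ns for water viscosity."""
    d_m2_s = kbt_joules(temperature) / (6.0 * 3.141592653589793 * WATER_VISCOSITY * radius_nm * 1e-9)
    return d_m2_s * 1e18 / 1e9  # m^2/s -> nm^2/ns
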