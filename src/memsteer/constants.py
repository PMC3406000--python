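"""Physical constants and unit conversions.

Internal unit system: lengths in Å, times in ps, energies in kT (so the
thermal factor k_BT never appears explicitly in the propagator), charges in
elementary charge e.
"""

import math

# SI
KB_SI = 1.380649e-23          # J/K
NA = 6.02214076e23            # 1/mol
E_CHARGE = 1.602176634e-19    # C
EPS0 = 8.8541878128e-12       # F/m

# chemistry units
KB_KCAL = 1.987204259e-3      # kcal mol^-1 K^-1
COULOMB_KCAL_A = 332.06371    # e^2/(4 pi eps0) in kcal Å / mol
DEBYE_PER_E_ANGSTROM = 4.80320425  # 1 e·Å in Debye

# printed hydrodynamic constants for the reference PH-domain system
D_TRANS_DEFAULT = 1.042e-6    # cm^2/s
D_ROT_DEFAULT = 1.656e7       # rad^2/s

# unit conversions
CM2_S_TO_A2_PS = 1e4          # 1 cm^2/s = 1e4 Å^2/ps
RAD2_S_TO_RAD2_PS = 1e-12
PS_TO_NS = 1e-3


def kt_kcal(temperature: float) -> float:
    """k_BT in kcal/mol."""
    return KB_KCAL * temperature


def coulomb_kt(temperature: float) -> float:
    """e^2/(4 pi eps0) expressed in (kT·Å)/e^2 at the given temperature.

    At 300 K this is ~557.0, i.e. the potential of a unit charge in vacuum
    at distance r Å is 557.0/r kT/e.
    """
    return COULOMB_KCAL_A / kt_kcal(temperature)


def debye_length_A(ionic_strength: float, temperature: float = 300.0,
                   eps_r: float = 78.5) -> float:
    """Debye screening length in Å for a monovalent electrolyte.

    kappa^-1 = sqrt(eps_r eps0 kB T / (2 NA e^2 * 1000 * I)), I in mol/L.
    """
    if ionic_strength <= 0 or temperature <= 0 or eps_r <= 0:
        raise ValueError("ionic_strength, temperature and eps_r must be positive")
    num = eps_r * EPS0 * KB_SI * temperature
    den = 2.0 * NA * E_CHARGE ** 2 * 1000.0 * ionic_strength
    return math.sqrt(num / den) * 1e10
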