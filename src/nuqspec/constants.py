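"""Physical constants and unit-conversion prefactors.

Internal unit system: length Å, time fs, energy eV, mass amu,
temperature K, wavenumber cm⁻¹.  Every derived prefactor below is
computed from CODATA SI values at import time so that identities such
as  var_wigner / var_classical = w(ν)  hold to machine precision.
"""

import math

# CODATA 2018 SI values
HBAR_J_S = 1.054571817e-34
C_CM_S = 2.99792458e10  # speed of light, cm/s
AMU_KG = 1.66053906660e-27
EV_J = 1.602176634e-19

#: hc in eV·cm — photon energy E[eV] = HC_EV_CM * wavenumber[cm⁻¹]
HC_EV_CM = 1.23984198e-4

#: Boltzmann constant, eV/K
KB_EV = 8.617333e-5

#: hc in eV·nm — wavelength λ[nm] = HC_EV_NM / E[eV]
HC_EV_NM = 1239.84198

#: 1 eV in kcal/mol
EV_TO_KCAL_MOL = 23.060548

#: harmonic force constant k = FORCE_CONST_PREF · m[amu] · ν̃²[cm⁻²]  in eV/Å²
FORCE_CONST_PREF = AMU_KG * (2.0 * math.pi * C_CM_S) ** 2 / EV_J * 1.0e-20

#: acceleration a[Å/fs²] = ACC_PREF · F[eV/Å] / m[amu]
ACC_PREF = EV_J / AMU_KG * 1.0e-10  # = 9.6485e-3

#: frequency conversion: f[cycles/fs] = ν̃[cm⁻¹] / CM_PER_CYCFS
CM_PER_CYCFS = 1.0e15 / C_CM_S  # ≈ 33356.41 cm⁻¹ per cycle/fs


def wavenumber_to_ev(nu_cm: float) -> float:
    """Photon/vibrational quantum energy hν in eV for wavenumber ν̃ in cm⁻¹."""
    return HC_EV_CM * nu_cm


def ev_to_wavenumber(e_ev: float) -> float:
    return e_ev / HC_EV_CM


def force_constant(nu_cm: float, mass_amu: float) -> float:
    """Harmonic force constant mω² in eV/Å²."""
    return FORCE_CONST_PREF * mass_amu * nu_cm * nu_cm


def vibrational_period_fs(nu_cm: float) -> float:
    """Period of a harmonic vibration of wavenumber ν̃, in fs."""
    return CM_PER_CYCFS / nu_cm
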