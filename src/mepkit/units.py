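"""Unit conversion constants.

Internal units are Hartree for energy and Ångström for length everywhere.
Quantities stated in other units (NEB spring constants in eV Å⁻¹, MM
convergence thresholds in kcal mol⁻¹ Å⁻¹, map energies in kcal mol⁻¹,
vibrational frequencies in cm⁻¹) are converted at the interface using the
constants below (CODATA 2018).
"""

HARTREE_TO_KCAL_PER_MOL = 627.5094740631
KCAL_PER_MOL_TO_HARTREE = 1.0 / HARTREE_TO_KCAL_PER_MOL

HARTREE_TO_EV = 27.211386245988
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV

HARTREE_TO_JOULE = 4.3597447222071e-18
ANGSTROM_TO_METER = 1e-10
AMU_TO_KG = 1.66053906660e-27
SPEED_OF_LIGHT_CM_S = 2.99792458e10

#: sqrt(Hartree / (amu Å²)) expressed as a wavenumber in cm⁻¹.
#: Used to convert mass-weighted Hessian eigenvalues to frequencies:
#: ν̃ = WAVENUMBER_FACTOR · sqrt(λ) for λ in Hartree Å⁻² amu⁻¹.
import math as _math

WAVENUMBER_FACTOR = (
    _math.sqrt(HARTREE_TO_JOULE / (AMU_TO_KG * ANGSTROM_TO_METER**2))
    / (2.0 * _math.pi * SPEED_OF_LIGHT_CM_S)
)
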