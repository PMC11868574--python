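"""Physical constants and unit conversions.

The canonical internal energy unit throughout the package is kcal/mol;
coordinates are in Angstrom, time in femtoseconds, masses in amu.
"""

#: kcal/mol per Hartree.
HARTREE_TO_KCAL = 627.509

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_MOL_K = 1.987204259e-3

#: Acceleration conversion: (kcal/mol/A) / amu -> A/fs^2.
#: 1 kcal/mol = 4184 J/mol; 1 A/fs^2 = 1e10/1e-30 m/s^2.
ACCEL_KCAL_PER_AMU_A = 4.184e-4

#: Kinetic-energy conversion: amu (A/fs)^2 -> kcal/mol (inverse of above).
KE_AMU_A2_FS2_TO_KCAL = 1.0 / ACCEL_KCAL_PER_AMU_A

KCAL_PER_HARTREE = HARTREE_TO_KCAL  # alias

ENERGY_UNIT_KCAL = "kcal/mol"
ENERGY_UNIT_HARTREE = "hartree"


def to_kcal_mol(value: float, unit: str) -> float:
    """Convert an energy in ``unit`` ('kcal/mol' or 'hartree') to kcal/mol."""
    if unit == ENERGY_UNIT_KCAL:
        return value
    if unit == ENERGY_UNIT_HARTREE:
        return value * HARTREE_TO_KCAL
    raise ValueError(f"unknown energy unit: {unit!r}")
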