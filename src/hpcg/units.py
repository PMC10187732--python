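"""Internal unit system and physical constants.

Energies are kcal/mol, lengths nm, times fs, masses g/mol.  Velocities are
nm/fs.  Forces in kcal/(mol nm) are converted to accelerations with
``KCAL_TO_INTERNAL`` (1 kcal/mol = 4.184e-6 g nm^2 / (fs^2 mol)).
"""

# Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

# Default simulation temperature, K
T_DEFAULT = 300.0

# kcal/mol expressed in g nm^2 fs^-2 mol^-1
KCAL_TO_INTERNAL = 4.184e-6

# Monomer mass, g/mol
BEAD_MASS = 100.0

# Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23


def kT(temperature: float = T_DEFAULT) -> float:
    """Thermal energy in kcal/mol."""
    return KB * temperature


def number_density_to_mg_per_ml(n_per_nm3: float, mass: float = BEAD_MASS) -> float:
    """Convert a bead number density (1/nm^3) to a mass concentration (mg/mL)."""
    # g/mol / (1/mol) = g per bead; nm^3 = 1e-21 mL; g/mL -> mg/mL is *1e3
    return n_per_nm3 * mass / N_AVOGADRO / 1e-21 * 1e3
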