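"""Internal unit system.

Lengths are measured in nanometres and number densities in molecules per
cubic nanometre, so that molecular volumes (4/3) pi r^3 multiplied by number
densities give dimensionless volume occupancies directly.  Public interfaces
(configs, CLI, kinetic parameters) speak micromolar; the conversion factor
below absorbs the Avogadro factors that otherwise appear in the occupancy
and growth-rate expressions.
"""

from scipy.constants import Avogadro

#: 1 uM expressed as molecules per nm^3 (1e-6 mol/L * N_A / 1e24 nm^3/L).
UM_TO_NM3 = Avogadro * 1e-30

#: Seconds per hour; rate constants are s^-1, growth rates reported in h^-1.
SECONDS_PER_HOUR = 3600.0


def um_to_number_density(conc_um: float) -> float:
    """Convert a concentration in uM to a number density in nm^-3."""
    return conc_um * UM_TO_NM3


def number_density_to_um(density_nm3: float) -> float:
    """Convert a number density in nm^-3 to a concentration in uM."""
    return density_nm3 / UM_TO_NM3
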