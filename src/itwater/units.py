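"""Unit constants. All internal computations use Hartree atomic units:
lengths in bohr, momenta in bohr^-1, energies in hartree, entropies in nats.
Interfaces that touch molecular geometry accept angstrom."""

from scipy.constants import physical_constants, k as _k_boltzmann

_BOHR_M = physical_constants["Bohr radius"][0]
_HARTREE_J = physical_constants["Hartree energy"][0]

#: bohr per angstrom (~1.8897)
BOHR_PER_ANGSTROM: float = 1e-10 / _BOHR_M

#: Boltzmann constant in hartree per kelvin (~3.1668e-6)
KB_HARTREE: float = _k_boltzmann / _HARTREE_J


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x / BOHR_PER_ANGSTROM
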