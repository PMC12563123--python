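"""Rigid three-site water models and their nonbonded pair potential.

A rigid three-site model is defined by a fixed monomer geometry (O-H bond
length and H-O-H angle), point charges on the three sites, and a single
Lennard-Jones site on the oxygen. The nonbonded interaction between two
molecules combines Lennard-Jones and Coulomb terms,

    V(r) = 4 eps_OO [ (sigma_OO/r)^12 - (sigma_OO/r)^6 ] + q_i q_j / r   (a.u.)

with cross interactions from the Lorentz-Berthelot mixing rules
sigma_ij = (sigma_ii + sigma_jj)/2 and eps_ij = sqrt(eps_ii * eps_jj).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import BOHR_PER_ANGSTROM, KB_HARTREE

__all__ = [
    "WaterGeometry",
    "ForceFieldParams",
    "TIP3P",
    "SPC",
    "SPCE_EPS",
    "BUILTIN_MODELS",
    "monomer_sites",
    "pair_potential",
    "lorentz_berthelot",
]


@dataclass(frozen=True)
class WaterGeometry:
    """Rigid monomer geometry: O-H bond length (angstrom) and H-O-H angle (deg)."""

    r_OH: float
    theta_HOH: float

    def __post_init__(self) -> None:
        if not self.r_OH > 0:
            raise ValueError(f"r_OH must be positive, got {self.r_OH}")
        if not 0.0 < self.theta_HOH < 180.0:
            raise ValueError(f"theta_HOH must lie in (0, 180) deg, got {self.theta_HOH}")


@dataclass(frozen=True)
class ForceFieldParams:
    """Parameters of a rigid three-site water model.

    Charges in units of e; sigma_OO in angstrom; eps_OO_over_kB in kelvin
    (the conventional way these models are tabulated).
    """

    name: str
    geometry: WaterGeometry
    q_H: float
    q_O: float
    sigma_OO: float
    eps_OO_over_kB: float

    def __post_init__(self) -> None:
        if abs(self.q_O + 2.0 * self.q_H) > 1e-9:
            raise ValueError(
                f"{self.name}: molecule not neutral (q_O + 2 q_H = {self.q_O + 2 * self.q_H:g})"
            )
        if not self.sigma_OO > 0:
            raise ValueError("sigma_OO must be positive")
        if not self.eps_OO_over_kB > 0:
            raise ValueError("eps_OO_over_kB must be positive")

    @property
    def eps_OO_hartree(self) -> float:
        return self.eps_OO_over_kB * KB_HARTREE

    @property
    def sigma_OO_bohr(self) -> float:
        return self.sigma_OO * BOHR_PER_ANGSTROM


TIP3P = ForceFieldParams(
    name="TIP3P",
    geometry=WaterGeometry(r_OH=0.9572, theta_HOH=104.52),
    q_H=+0.417,
    q_O=-0.834,
    sigma_OO=3.1506,
    eps_OO_over_kB=76.54,
)

SPC = ForceFieldParams(
    name="SPC",
    geometry=WaterGeometry(r_OH=1.0, theta_HOH=109.45),
    q_H=+0.410,
    q_O=-0.820,
    sigma_OO=3.1660,
    eps_OO_over_kB=78.20,
)

#: SPC/eps — SPC geometry with charges re-optimized against the experimental
#: static dielectric constant.
SPCE_EPS = ForceFieldParams(
    name="SPC/e",
    geometry=WaterGeometry(r_OH=1.0, theta_HOH=109.45),
    q_H=+0.445,
    q_O=-0.890,
    sigma_OO=3.1785,
    eps_OO_over_kB=84.90,
)

BUILTIN_MODELS: dict[str, ForceFieldParams] = {
    "TIP3P": TIP3P,
    "SPC": SPC,
    "SPC/e": SPCE_EPS,
}


def monomer_sites(ff: ForceFieldParams) -> np.ndarray:
    """Site coordinates (angstrom) of a rigid monomer, rows (O, H1, H2).

    The oxygen sits at the origin and the two hydrogens lie in the xy-plane,
    symmetric about the +x axis (the dipole axis).
    """
    half = math.radians(ff.geometry.theta_HOH) / 2.0
    r = ff.geometry.r_OH
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [r * math.cos(half), r * math.sin(half), 0.0],
            [r * math.cos(half), -r * math.sin(half), 0.0],
        ]
    )


def lorentz_berthelot(ff_i: ForceFieldParams, ff_j: ForceFieldParams) -> tuple[float, float]:
    """Cross O-O parameters (sigma_ij angstrom, eps_ij/kB kelvin)."""
    sigma = 0.5 * (ff_i.sigma_OO + ff_j.sigma_OO)
    eps = math.sqrt(ff_i.eps_OO_over_kB * ff_j.eps_OO_over_kB)
    return sigma, eps


def pair_potential(
    r: float,
    ff_i: ForceFieldParams,
    ff_j: ForceFieldParams | None = None,
    *,
    include_lj: bool = True,
    include_coulomb: bool = True,
) -> float:
    """O-O site-pair interaction energy V(r) in hartree, r in angstrom.

    The Lennard-Jones term uses Lorentz-Berthelot cross parameters; the
    Coulomb term is the O-O charge product q_O,i * q_O,j / r in atomic units
    (vacuum permittivity absorbed by the unit system). Either term can be
    switched off to inspect the other in isolation.
    """
    if ff_j is None:
        ff_j = ff_i
    if not r > 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    r_bohr = r * BOHR_PER_ANGSTROM
    v = 0.0
    if include_lj:
        sigma, eps_k = lorentz_berthelot(ff_i, ff_j)
        sr6 = (sigma * BOHR_PER_ANGSTROM / r_bohr) ** 6
        v += 4.0 * eps_k * KB_HARTREE * (sr6 * sr6 - sr6)
    if include_coulomb:
        v += ff_i.q_O * ff_j.q_O / r_bohr
    return v
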