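"""Information-theoretic descriptors of a 3D probability density.

Five measures are computed, in position (r) and momentum (p) space:

* Shannon entropy        S = -∫ rho ln rho      (nats; global dispersion)
* Fisher information     I = ∫ |grad rho|^2/rho (a.u.; local sharpness)
* Disequilibrium         D = ∫ rho^2            (a.u.; deviation from uniformity)
* LMC complexity         C_LMC = D * e^S        (dimensionless, >= 1)
* Fisher-Shannon         C_FS = I * J,  J = e^(2S/3) / (2*pi*e)
                         (dimensionless, >= 3; equality for Gaussians)

Both complexities are invariant under translation and dilation of the
density; the lower bounds hold for any 3D probability density, with the
isotropic Gaussian attaining C_FS = 3 exactly.  Complexities are assembled
from the already-integrated S, I, D, so an apparent bound violation points
at the quadrature, not at the formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .density import (
    GridDensity,
    MixtureDensity,
    QuadratureSpec,
    information_integrals,
    integrate,
    momentum_conjugate,
)

__all__ = [
    "DescriptorSet",
    "shannon_entropy",
    "fisher_information",
    "disequilibrium",
    "lmc_complexity",
    "fs_complexity",
    "descriptor_set",
    "MEASURES",
]

#: canonical measure labels used in sample tables and CSV output
MEASURES = ("S", "I", "D", "C_LMC", "C_FS")


@dataclass(frozen=True)
class DescriptorSet:
    """The ten descriptor values for one configuration.

    Momentum-space fields are ``None`` for grid-backed densities, where no
    analytic conjugate exists.
    """

    S_r: float
    I_r: float
    D_r: float
    C_LMC_r: float
    C_FS_r: float
    S_p: float | None
    I_p: float | None
    D_p: float | None
    C_LMC_p: float | None
    C_FS_p: float | None
    quad_error: float

    def as_dict(self) -> dict[str, float | None]:
        return {
            "S_r": self.S_r,
            "I_r": self.I_r,
            "D_r": self.D_r,
            "C_LMC_r": self.C_LMC_r,
            "C_FS_r": self.C_FS_r,
            "S_p": self.S_p,
            "I_p": self.I_p,
            "D_p": self.D_p,
            "C_LMC_p": self.C_LMC_p,
            "C_FS_p": self.C_FS_p,
        }

    def values_for_space(self, space: str) -> dict[str, float | None]:
        """Measure -> value mapping for space 'r' or 'p'."""
        if space not in ("r", "p"):
            raise ValueError("space must be 'r' or 'p'")
        d = self.as_dict()
        return {m: d[f"{m}_{space}"] for m in MEASURES}


def shannon_entropy(density, quad: QuadratureSpec | None = None) -> float:
    """S = -∫ rho ln rho, in nats (natural log)."""
    return -integrate("density*log(density)", density, quad).value


def fisher_information(density, quad: QuadratureSpec | None = None) -> float:
    """I = ∫ |grad rho|^2 / rho."""
    return integrate("grad2/density", density, quad).value


def disequilibrium(density, quad: QuadratureSpec | None = None) -> float:
    """D = ∫ rho^2."""
    return integrate("density^2", density, quad).value


def lmc_complexity(D: float, S: float) -> float:
    """C_LMC = D * e^S; >= 1 for any 3D probability density."""
    if not D > 0:
        raise ValueError(f"disequilibrium must be positive, got {D}")
    return D * math.exp(S)


def fs_complexity(I: float, S: float) -> float:
    """C_FS = I * J with power entropy J = e^(2S/3)/(2*pi*e); >= 3."""
    if not I > 0:
        raise ValueError(f"Fisher information must be positive, got {I}")
    J = math.exp(2.0 * S / 3.0) / (2.0 * math.pi * math.e)
    return I * J


def descriptor_set(
    density_r: MixtureDensity | GridDensity,
    quad: QuadratureSpec | None = None,
) -> DescriptorSet:
    """All ten descriptors of a position-space density.

    For a mixture the momentum leg is computed on the analytic conjugate;
    for a grid density the momentum leg is emitted as ``None``.
    """
    if isinstance(density_r, MixtureDensity):
        if density_r.space != "position":
            raise ValueError("descriptor_set expects a position-space density")
        S_r, I_r, D_r, err_r = information_integrals(density_r, quad)
        gamma = momentum_conjugate(density_r)
        S_p, I_p, D_p, err_p = information_integrals(gamma, quad)
        return DescriptorSet(
            S_r=S_r,
            I_r=I_r,
            D_r=D_r,
            C_LMC_r=lmc_complexity(D_r, S_r),
            C_FS_r=fs_complexity(I_r, S_r),
            S_p=S_p,
            I_p=I_p,
            D_p=D_p,
            C_LMC_p=lmc_complexity(D_p, S_p),
            C_FS_p=fs_complexity(I_p, S_p),
            quad_error=max(err_r, err_p),
        )
    # grid-backed density: position leg only
    S_r = shannon_entropy(density_r, quad)
    I_r = fisher_information(density_r, quad)
    D_r = disequilibrium(density_r, quad)
    return DescriptorSet(
        S_r=S_r,
        I_r=I_r,
        D_r=D_r,
        C_LMC_r=lmc_complexity(D_r, S_r),
        C_FS_r=fs_complexity(I_r, S_r),
        S_p=None,
        I_p=None,
        D_p=None,
        C_LMC_p=None,
        C_FS_p=None,
        quad_error=0.0,
    )
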