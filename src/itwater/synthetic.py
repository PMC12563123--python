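"""Synthetic water-like electron densities and descriptor sample tables.

Real per-frame descriptor samples come from MD snapshots fed through DFT;
this module emulates the same data shapes analytically so that every
downstream stage (descriptors, clustering, statistics) is testable without
simulations.  Each atom carries one isotropic Gaussian; a configuration's
density is the normalized mixture over all atoms.  Two weighting modes:

* ``electron_count`` — weights proportional to the neutral-atom electron
  counts (O: 8, H: 1).  Models sharing a geometry (SPC and SPC/eps) then
  produce *identical* densities.
* ``charge_perturbed`` — weights proportional to Z - q, the electron count
  implied by the force field's partial charge q, so SPC and SPC/eps differ
  while sharing a geometry.  A surrogate, not a claim about real densities.

Frame-to-frame variability is modeled as small isotropic Gaussian jitter of
the atomic centers, standing in for the constraint-algorithm and integration
noise that perturbs nominally rigid monomers in MD.  Everything is seeded
and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import Frame
from .density import GaussianComponent, MixtureDensity, QuadratureSpec
from .descriptors import MEASURES, descriptor_set
from .forcefield import ForceFieldParams, monomer_sites
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "EnsembleSpec",
    "GenerationError",
    "DEFAULT_WIDTHS",
    "make_monomer_density",
    "configuration_density",
    "make_cluster_configuration",
    "make_descriptor_samples",
    "random_mixture_density",
]

#: default per-atom Gaussian widths in bohr; arbitrary but fixed — only
#: relative differences between models matter for the comparisons made here
DEFAULT_WIDTHS = {"O": 0.45, "H": 0.65}

#: neutral-atom electron counts used by both weighting modes
_ELECTRONS = {"O": 8.0, "H": 1.0}

#: placement attempts per molecule before giving up
RETRY_BUDGET = 1000


class GenerationError(RuntimeError):
    """Raised when rigid-body placement exhausts its retry budget."""


@dataclass(frozen=True)
class EnsembleSpec:
    """How many molecules/frames to generate and with what variability.

    jitter_sigma (angstrom) is the per-coordinate standard deviation of the
    atomic-center jitter applied independently to every frame.
    oo_distance_range (angstrom) brackets nearest-neighbor O-O distances in
    generated cluster configurations.
    """

    n_molecules: int = 1
    n_frames: int = 30
    jitter_sigma: float = 0.01
    oo_distance_range: tuple[float, float] = (2.6, 3.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        lo, hi = self.oo_distance_range
        if not 0 < lo <= hi:
            raise ValueError("oo_distance_range must satisfy 0 < lo <= hi")


def _atom_arrays(
    n_molecules: int,
    ff: ForceFieldParams,
    widths: dict[str, float] | None,
    weight_mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(sigmas, weights) for 3*n_molecules atoms in O,H,H molecule order."""
    widths = widths or DEFAULT_WIDTHS
    for el, w in widths.items():
        if not w > 0:
            raise ValueError(f"width for {el} must be positive, got {w}")
    if weight_mode == "electron_count":
        per_atom = {el: _ELECTRONS[el] for el in ("O", "H")}
    elif weight_mode == "charge_perturbed":
        # electron count implied by the model's partial charges: Z - q
        per_atom = {"O": _ELECTRONS["O"] - ff.q_O, "H": _ELECTRONS["H"] - ff.q_H}
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    elements = ("O", "H", "H") * n_molecules
    sigmas = np.array([widths[el] for el in elements])
    weights = np.array([per_atom[el] for el in elements])
    return sigmas, weights / weights.sum()


def configuration_density(
    sites_angstrom: np.ndarray,
    ff: ForceFieldParams,
    widths: dict[str, float] | None = None,
    weight_mode: str = "electron_count",
) -> MixtureDensity:
    """Mixture density for an arbitrary (3n, 3) site array (O,H,H order, angstrom)."""
    sites = np.asarray(sites_angstrom, dtype=float)
    if sites.ndim != 2 or sites.shape[1] != 3 or sites.shape[0] % 3 != 0:
        raise ValueError(f"sites must be (3n, 3), got {sites.shape}")
    n_mol = sites.shape[0] // 3
    sigmas, weights = _atom_arrays(n_mol, ff, widths, weight_mode)
    return MixtureDensity.from_parts(sites * BOHR_PER_ANGSTROM, sigmas, weights)


def make_monomer_density(
    ff: ForceFieldParams,
    widths: dict[str, float] | None = None,
    weight_mode: str = "electron_count",
) -> MixtureDensity:
    """Unit-normalized 3-Gaussian density of one rigid monomer of ``ff``."""
    return configuration_density(monomer_sites(ff), ff, widths, weight_mode)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_cluster_configuration(ff: ForceFieldParams, spec: EnsembleSpec) -> Frame:
    """Seeded rigid-body placement of ``spec.n_molecules`` waters.

    Molecules are attached one at a time at a distance drawn from
    ``oo_distance_range`` from a random previously placed oxygen, in a random
    direction and orientation; candidates bringing any O-O distance below
    the range minimum are rejected.  Every molecule's nearest-neighbor O-O
    distance therefore lies inside the range, and the whole configuration is
    connected at any cutoff >= the range maximum.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = monomer_sites(ff)
    lo, hi = spec.oo_distance_range

    def place(origin: np.ndarray) -> np.ndarray:
        return base @ _random_rotation(rng).T + origin

    molecules = [place(np.zeros(3))]
    for _ in range(1, spec.n_molecules):
        placed = False
        for _attempt in range(RETRY_BUDGET):
            anchor = molecules[rng.integers(len(molecules))][0]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            new_o = anchor + rng.uniform(lo, hi) * direction
            existing = np.array([m[0] for m in molecules])
            if np.all(np.linalg.norm(existing - new_o, axis=1) >= lo):
                molecules.append(place(new_o))
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place molecule {len(molecules) + 1}/{spec.n_molecules} "
                f"within {RETRY_BUDGET} attempts (oo_distance_range={spec.oo_distance_range})"
            )
    return Frame(molecules=molecules)


def make_descriptor_samples(
    ff: ForceFieldParams,
    spec: EnsembleSpec,
    *,
    widths: dict[str, float] | None = None,
    weight_mode: str = "electron_count",
    quad: QuadratureSpec | None = None,
) -> pd.DataFrame:
    """Per-frame descriptor sample table for one (model, cluster size).

    For each frame the base configuration's atomic centers are jittered with
    isotropic Gaussian noise of ``spec.jitter_sigma``, the mixture density is
    rebuilt, and the full descriptor set is computed.  Long-format columns:
    model, size, frame, space ('r'/'p'), measure, value.  Bit-identical for
    a fixed spec — models sharing geometry, widths and weights yield equal
    tables under the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_molecules == 1:
        base_sites = monomer_sites(ff)
    else:
        base_sites = make_cluster_configuration(ff, spec).all_sites()
    rows = []
    for frame_idx in range(spec.n_frames):
        jitter = rng.normal(scale=spec.jitter_sigma, size=base_sites.shape)
        density = configuration_density(base_sites + jitter, ff, widths, weight_mode)
        ds = descriptor_set(density, quad)
        for space in ("r", "p"):
            for measure, value in ds.values_for_space(space).items():
                rows.append(
                    {
                        "model": ff.name,
                        "size": spec.n_molecules,
                        "frame": frame_idx,
                        "space": space,
                        "measure": measure,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows, columns=["model", "size", "frame", "space", "measure", "value"])


def random_mixture_density(
    rng: np.random.Generator,
    n_components: int | None = None,
    *,
    max_components: int = 12,
    center_halfwidth: float = 4.0,
    sigma_range: tuple[float, float] = (0.4, 1.5),
) -> MixtureDensity:
    """Random unit-normalized Gaussian mixture for property sweeps.

    Centers uniform in a cube of half-width ``center_halfwidth`` bohr, widths
    uniform in ``sigma_range``, weights Dirichlet(1).  Used to exercise the
    universal complexity bounds C_LMC >= 1 and C_FS >= 3.
    """
    if n_components is None:
        n_components = int(rng.integers(1, max_components + 1))
    centers = rng.uniform(-center_halfwidth, center_halfwidth, size=(n_components, 3))
    sigmas = rng.uniform(*sigma_range, size=n_components)
    weights = rng.dirichlet(np.ones(n_components))
    return MixtureDensity.from_parts(centers, sigmas, weights)
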