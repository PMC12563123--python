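"""Gaussian CUBE volumetric file I/O.

Standard layout: two comment lines; a record with the atom count and grid
origin; three axis records (voxel count + axis vector); one record per atom
(Z, charge, x, y, z); then the voxel data with the z index fastest.  A
negative voxel count on an axis record flags axis vectors given in angstrom
(converted here to bohr); positive counts mean bohr.  Only orthogonal,
axis-aligned grids are supported.

Negative voxel values (common in difference densities) are clamped to zero
with a logged count, and the grid is renormalized to unit Riemann mass, so
the result is directly usable as a probability density.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .density import GridDensity
from .units import BOHR_PER_ANGSTROM

logger = logging.getLogger(__name__)

__all__ = ["read_cube", "write_cube", "CubeParseError"]


class CubeParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _floats(tokens, path, lineno):
    try:
        return [float(t) for t in tokens]
    except ValueError as exc:
        raise CubeParseError(path, lineno, f"expected numeric fields, got {tokens!r}") from exc


def read_cube(path, *, normalize: bool = True) -> GridDensity:
    """Read a CUBE file into a :class:`GridDensity` (bohr, unit mass)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise CubeParseError(path, len(lines), "truncated header")

    fields = lines[2].split()
    if len(fields) < 4:
        raise CubeParseError(path, 3, "expected: natoms origin_x origin_y origin_z")
    vals = _floats(fields[:4], path, 3)
    natoms = int(vals[0])
    # negative natoms flags an orbital-id record after the atom block
    has_dset = natoms < 0
    natoms = abs(natoms)
    origin = np.array(vals[1:4])

    shape = []
    spacing = []
    for d in range(3):
        fields = lines[3 + d].split()
        if len(fields) < 4:
            raise CubeParseError(path, 4 + d, "expected: nvoxels axis_x axis_y axis_z")
        vals = _floats(fields[:4], path, 4 + d)
        n = int(vals[0])
        axis = np.array(vals[1:4])
        if n < 0:  # angstrom convention
            n = -n
            axis = axis * BOHR_PER_ANGSTROM
        off_diag = np.delete(axis, d)
        if np.any(np.abs(off_diag) > 1e-12 * max(1.0, abs(axis[d]))):
            raise CubeParseError(path, 4 + d, f"non-axis-aligned grid vector {axis} unsupported")
        if axis[d] <= 0:
            raise CubeParseError(path, 4 + d, f"axis {d} step must be positive, got {axis[d]}")
        shape.append(n)
        spacing.append(axis[d])

    first_data = 6 + natoms + (1 if has_dset else 0)
    tokens: list[str] = []
    for line in lines[first_data:]:
        tokens.extend(line.split())
    expected = shape[0] * shape[1] * shape[2]
    if len(tokens) < expected:
        raise CubeParseError(
            path, len(lines), f"expected {expected} voxel values, found {len(tokens)}"
        )
    data = np.array(tokens[:expected], dtype=float).reshape(shape)  # z fastest

    n_negative = int(np.sum(data < 0))
    if n_negative:
        logger.warning("%s: clamped %d negative voxels to 0", path.name, n_negative)
        data = np.maximum(data, 0.0)

    grid = GridDensity(origin=origin, spacing=np.array(spacing), values=data)
    if normalize and abs(grid.total_mass() - 1.0) > 1e-12:
        grid = grid.normalized()
    return grid


def write_cube(grid: GridDensity, path, *, atoms=None, comment: str = "itwater density") -> None:
    """Write a :class:`GridDensity` as a CUBE file.

    ``atoms`` is an optional iterable of (Z, x, y, z) in bohr; omitted atoms
    produce a zero-atom cube, which readers accept.
    """
    path = Path(path)
    atoms = list(atoms or [])
    with path.open("w") as fh:
        fh.write(f"{comment}\n")
        fh.write("generated by itwater\n")
        fh.write(
            f"{len(atoms):5d} {grid.origin[0]:.17g} {grid.origin[1]:.17g} "
            f"{grid.origin[2]:.17g}\n"
        )
        for d in range(3):
            axis = [0.0, 0.0, 0.0]
            axis[d] = grid.spacing[d]
            fh.write(f"{grid.shape[d]:5d} {axis[0]:.17g} {axis[1]:.17g} {axis[2]:.17g}\n")
        for z, x, y, zz in atoms:
            fh.write(f"{int(z):5d} {float(z):12.6f} {x:12.6f} {y:12.6f} {zz:12.6f}\n")
        flat = grid.values.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
        for row in flat:
            for start in range(0, row.size, 6):
                chunk = row[start : start + 6]
                fh.write(" ".join(f"{v:.16E}" for v in chunk) + "\n")
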