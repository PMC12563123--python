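"""Water cluster identification by the Sevick oxygen-oxygen distance criterion.

Two molecules are directly linked when their O-O distance is at most the
cutoff ``r_cut``; clusters are the connected components of the resulting
graph, so linkage is transitive.  The cutoff is a required, visible choice:
the conventional default of 3.5 angstrom corresponds to the first minimum of
the O-O radial distribution function of liquid water.  Orthorhombic periodic
boxes are handled by the minimum-image convention; frames without a box use
raw distances.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Frame",
    "ClusterSet",
    "DEFAULT_R_CUT",
    "sevick_clusters",
    "harvest_by_size",
    "read_xyz",
    "write_xyz",
]

#: conventional first-minimum of g_OO(r) in liquid water, angstrom
DEFAULT_R_CUT = 3.5


@dataclass
class Frame:
    """Molecular coordinates of one snapshot.

    ``molecules`` is a list of (3, 3) arrays in angstrom with rows
    (O, H1, H2).  ``box`` is an optional orthorhombic box (3 lengths,
    angstrom); ``time`` an integer frame index.
    """

    molecules: list[np.ndarray]
    box: np.ndarray | None = None
    time: int = 0

    def __post_init__(self) -> None:
        self.molecules = [np.asarray(m, dtype=float) for m in self.molecules]
        for m in self.molecules:
            if m.shape != (3, 3):
                raise ValueError(f"each molecule needs exactly 3 sites, got shape {m.shape}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 positive lengths")

    def __len__(self) -> int:
        return len(self.molecules)

    def oxygens(self) -> np.ndarray:
        """(n, 3) oxygen positions in angstrom."""
        return np.array([m[0] for m in self.molecules]).reshape(len(self.molecules), 3)

    def all_sites(self) -> np.ndarray:
        """(3n, 3) site positions in angstrom, molecule-major order O,H,H."""
        return np.concatenate(self.molecules, axis=0) if self.molecules else np.empty((0, 3))


@dataclass(frozen=True)
class ClusterSet:
    """Partition of molecules into clusters.

    ``partition[i]`` is the cluster id of molecule i; ``sizes`` the multiset
    of cluster sizes.
    """

    partition: tuple[int, ...]
    sizes: Counter = field(default_factory=Counter)

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "ClusterSet":
        labels = np.asarray(labels, dtype=int)
        return cls(partition=tuple(labels.tolist()), sizes=Counter(Counter(labels.tolist()).values()))

    @property
    def n_clusters(self) -> int:
        return len(set(self.partition))

    def members(self, cluster_id: int) -> list[int]:
        return [i for i, c in enumerate(self.partition) if c == cluster_id]


def _oo_distance_matrix(frame: Frame) -> np.ndarray:
    oxy = frame.oxygens()
    diff = oxy[:, None, :] - oxy[None, :, :]
    if frame.box is not None:
        diff -= frame.box * np.round(diff / frame.box)
    return np.sqrt(np.sum(diff**2, axis=-1))


def sevick_clusters(frame: Frame, r_cut: float = DEFAULT_R_CUT) -> ClusterSet:
    """Partition the frame into clusters by transitive O-O linkage.

    Coincident oxygens (distance 0) are valid and always linked.
    """
    if not r_cut > 0:
        raise ValueError(f"r_cut must be positive, got {r_cut}")
    n = len(frame)
    if n == 0:
        return ClusterSet(partition=(), sizes=Counter())
    adj = _oo_distance_matrix(frame) <= r_cut
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return ClusterSet.from_labels(labels)


def harvest_by_size(
    frames: list[Frame],
    r_cut: float = DEFAULT_R_CUT,
    wanted_sizes: set[int] | None = None,
    stride: int = 1,
) -> dict[int, list[tuple[int, int]]]:
    """Collect every (frame index, cluster id) occurrence per wanted size.

    ``stride`` subsamples the frame list (cluster searches need not run at
    the trajectory save cadence).  Sizes never observed map to empty lists.
    """
    if not wanted_sizes:
        raise ValueError("wanted_sizes must be a non-empty set")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out: dict[int, list[tuple[int, int]]] = {s: [] for s in sorted(wanted_sizes)}
    for fi in range(0, len(frames), stride):
        cs = sevick_clusters(frames[fi], r_cut)
        counts = Counter(cs.partition)
        for cid, size in counts.items():
            if size in out:
                out[size].append((fi, cid))
    return out


# ---------------------------------------------------------------------------
# XYZ I/O: element, x, y, z per line; molecules are consecutive O,H,H records


def write_xyz(frames: Frame | list[Frame], path, comment: str = "itwater frame") -> None:
    if isinstance(frames, Frame):
        frames = [frames]
    with Path(path).open("w") as fh:
        for fr in frames:
            fh.write(f"{3 * len(fr)}\n")
            fh.write(f"{comment} time={fr.time}\n")
            for mol in fr.molecules:
                for el, site in zip(("O", "H", "H"), mol):
                    fh.write(f"{el} {site[0]:.8f} {site[1]:.8f} {site[2]:.8f}\n")


def read_xyz(path) -> list[Frame]:
    """Read a (multi-frame) XYZ file, grouping consecutive O,H,H records."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    t = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].split()[0])
        if natoms % 3 != 0:
            raise ValueError(f"{path}: atom count {natoms} is not a multiple of 3")
        block = lines[i + 2 : i + 2 + natoms]
        sites = []
        elements = []
        for line in block:
            parts = line.split()
            elements.append(parts[0])
            sites.append([float(parts[1]), float(parts[2]), float(parts[3])])
        mols = []
        for m in range(natoms // 3):
            if elements[3 * m : 3 * m + 3] != ["O", "H", "H"]:
                raise ValueError(
                    f"{path}: molecule {m} records are {elements[3 * m:3 * m + 3]}, expected O,H,H"
                )
            mols.append(np.array(sites[3 * m : 3 * m + 3]))
        frames.append(Frame(molecules=mols, time=t))
        t += 1
        i += 2 + natoms
    return frames
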