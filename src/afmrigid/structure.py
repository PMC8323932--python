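"""Atomic models, rigid transforms, stage grounding and structure-RMSD.

Coordinates are stored in nanometres throughout the package; the PDB
boundary (Angstrom) converts on read/write.  Atoms carry a per-atom
collision radius used by the probe collision detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptyModelError,
    FormatError,
    ShapeMismatchError,
)

log = logging.getLogger(__name__)

NM_PER_ANGSTROM = 0.1

#: Van der Waals radii in nm used for collision detection, by element symbol.
VDW_RADII_NM = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "H": 0.120,
    "P": 0.180,
}

#: Fallback radius (nm) for elements missing from the table (carbon-like).
DEFAULT_RADIUS_NM = 0.170


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion ``x -> rotation @ x + translation`` (nm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation is improper (det < 0)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class AtomicModel:
    """Atoms with coordinates (nm) and per-atom collision radii (nm).

    ``labels`` is opaque metadata (a biotite ``AtomArray`` for models read
    from PDB files, anything hashable-free for synthetic models); it is
    carried along unchanged by geometric operations.
    """

    positions: np.ndarray
    radii: np.ndarray
    labels: Optional[object] = field(default=None, compare=False)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        rad = np.asarray(self.radii, dtype=float).reshape(-1)
        if pos.shape[0] != rad.shape[0]:
            raise ShapeMismatchError(
                f"{pos.shape[0]} positions but {rad.shape[0]} radii"
            )
        if pos.size and not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if rad.size and not np.all(rad > 0):
            raise ValueError("radii must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "radii", rad)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def transformed(self, transform: RigidTransform) -> "AtomicModel":
        return replace(self, positions=transform.apply(self.positions))

    def translated(self, shift) -> "AtomicModel":
        return replace(self, positions=self.positions + np.asarray(shift, float))


def _element_radius(element: str, atom_name: str) -> float:
    el = element.strip().upper()
    if el in VDW_RADII_NM:
        return VDW_RADII_NM[el]
    # element field absent or unknown: infer from the first letter of the name
    name = atom_name.strip()
    guess = name.lstrip("0123456789")[:1].upper()
    if guess in VDW_RADII_NM:
        return VDW_RADII_NM[guess]
    log.warning("unknown element %r (atom %r): using default radius", element, atom_name)
    return DEFAULT_RADIUS_NM


def read_structure(
    path,
    radius_scheme: str = "vdw",
    uniform_radius_nm: float = 0.2,
    include_hetatm: bool = True,
    exclude_waters: bool = True,
) -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel` (coordinates in nm).

    Parameters
    ----------
    radius_scheme:
        ``"vdw"`` assigns per-element van der Waals radii; ``"uniform"``
        assigns ``uniform_radius_nm`` to every atom.
    include_hetatm:
        Keep HETATM records (waters are dropped separately by default).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if radius_scheme not in ("vdw", "uniform"):
        raise ValueError(f"unknown radius scheme {radius_scheme!r}")
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc

    keep = np.ones(atoms.array_length(), dtype=bool)
    if not include_hetatm:
        keep &= ~atoms.hetero
    if exclude_waters:
        keep &= ~struc.filter_solvent(atoms)
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise EmptyModelError(f"no atoms read from {path}")

    positions = atoms.coord * NM_PER_ANGSTROM
    if radius_scheme == "uniform":
        radii = np.full(atoms.array_length(), float(uniform_radius_nm))
    else:
        radii = np.array(
            [
                _element_radius(el, nm)
                for el, nm in zip(atoms.element, atoms.atom_name)
            ]
        )
    return AtomicModel(positions, radii, labels=atoms)


def write_structure(model: AtomicModel, path) -> None:
    """Write a model to a PDB file (nm converted back to Angstrom).

    Models read from a PDB keep their original annotations; synthetic
    models are written as pseudo-atoms (CA carbons, one residue per atom).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(model)
    if isinstance(model.labels, struc.AtomArray) and model.labels.array_length() == n:
        atoms = model.labels.copy()
    else:
        atoms = struc.AtomArray(n)
        atoms.chain_id = np.full(n, "A")
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.full(n, "GLY")
        atoms.atom_name = np.full(n, "CA")
        atoms.element = np.full(n, "C")
        atoms.hetero = np.zeros(n, dtype=bool)
    atoms.coord = np.asarray(model.positions / NM_PER_ANGSTROM, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def pca_obb_axes(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Oriented-bounding-box axes from principal component analysis.

    Axis 1 is the first principal component; axis 2 is the second principal
    component re-orthogonalized against axis 1; axis 3 is their cross
    product.  Axis signs follow a deterministic convention (the component
    of largest magnitude is positive) so repeated calls agree.

    Returns ``(axes, extents)`` where ``axes`` rows are the three unit
    vectors and ``extents`` the side lengths of the bounding box along them.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 atoms for an OBB")
    centered = pos - pos.mean(axis=0)
    # principal components via SVD of the centered coordinates
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise DegenerateGeometryError("point set is (near-)collinear")
    a1 = vt[0]
    a2 = vt[1] - (vt[1] @ a1) * a1
    a2 /= np.linalg.norm(a2)
    a3 = np.cross(a1, a2)

    axes = np.vstack([a1, a2, a3])
    for i in range(3):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    # restore right-handedness after sign fixing
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    proj = centered @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    return axes, extents


def rest_on_stage(model: AtomicModel) -> AtomicModel:
    """Translate so the lowest sphere touches the stage: min(z - radius) = 0."""
    dz = np.min(model.positions[:, 2] - model.radii)
    return model.translated((0.0, 0.0, -dz))


def ground_on_stage(model: AtomicModel) -> AtomicModel:
    """Rotate the largest OBB face onto the stage and rest the model on z=0.

    Mimics weak physisorption in AFM sample preparation: the molecule is
    assumed to lie on its broadest face.  The two largest-extent OBB axes
    are mapped to X and Y (largest to X), the smallest to Z; the model is
    then centred at the XY origin and dropped so ``min(z - radius) = 0``.
    """
    if len(model) == 0:
        raise EmptyModelError("cannot ground an empty model")
    axes, extents = pca_obb_axes(model.positions)
    # stable sort: on ties the earlier PCA axis stays horizontal, so the
    # face normal defaults to the third axis
    order = np.argsort(-extents, kind="stable")
    rot = axes[order]
    if np.linalg.det(rot) < 0:
        rot[2] = -rot[2]
    centroid = model.centroid
    new_pos = (model.positions - centroid) @ rot.T
    new_pos[:, :2] -= new_pos[:, :2].mean(axis=0)
    grounded = replace(model, positions=new_pos)
    return rest_on_stage(grounded)


def structure_rmsd(a: AtomicModel, b: AtomicModel) -> float:
    """Root-mean-square deviation between matched atoms, in nm.

    No superposition is performed: the deviation is measured in the frames
    the models already sit in, so placement errors count.
    """
    if len(a) != len(b):
        raise ShapeMismatchError(f"atom counts differ: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise EmptyModelError("empty models")
    diff = a.positions - b.positions
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def windowed_filament_rmsd(
    pred: AtomicModel, truth: AtomicModel, monomer_atoms: int
) -> float:
    """Minimum structure-RMSD of ``pred`` over consecutive windows of ``truth``.

    Both models must be filaments whose atoms are ordered monomer by
    monomer with ``monomer_atoms`` atoms each.  ``pred`` (a k-mer) is
    compared against every consecutive k-monomer window of ``truth`` (an
    m-mer, m >= k) and the smallest RMSD is returned, so a sub-filament
    fit is scored against its best registration.
    """
    if monomer_atoms <= 0:
        raise ValueError("monomer_atoms must be positive")
    for name, m in (("pred", pred), ("truth", truth)):
        if len(m) % monomer_atoms != 0:
            raise ShapeMismatchError(
                f"{name} atom count {len(m)} is not a multiple of {monomer_atoms}"
            )
    k = len(pred) // monomer_atoms
    m = len(truth) // monomer_atoms
    if k > m:
        raise ShapeMismatchError(f"window of {k} monomers exceeds truth ({m})")
    best = np.inf
    for start in range(m - k + 1):
        window = AtomicModel(
            truth.positions[start * monomer_atoms : (start + k) * monomer_atoms],
            truth.radii[start * monomer_atoms : (start + k) * monomer_atoms],
        )
        best = min(best, structure_rmsd(pred, window))
    return float(best)
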