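"""Synthetic ground-truth generators for twin experiments and tests.

Real targets of this kind of fitting are large, anisotropic proteins
(molecular motors, filaments).  These generators build stand-ins with the
same gross geometry — an anisotropic blob of spheres, and a helical
filament with actin-like rise — without claiming structural fidelity to
any particular molecule.  Everything is seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .imaging import HeightMap, ProbeShape, add_noise, render
from .structure import AtomicModel, RigidTransform, ground_on_stage


def make_blob(
    n_atoms: int,
    extent: tuple[float, float, float] = (12.0, 8.0, 5.0),
    seed: int = 0,
    radius: float = 0.5,
    n_domains: int = 10,
    domain_sd: float = 1.2,
) -> AtomicModel:
    """Anisotropic, corrugated cluster of spheres spanning ``extent`` nm.

    Atoms are grouped into ``n_domains`` Gaussian clumps (sd
    ``domain_sd`` nm) whose centres are drawn uniformly in an ellipsoid;
    the whole cloud is rescaled per axis so the spans match ``extent``
    exactly.  The clumps give the surface nm-scale corrugation like the
    domain structure of a large multi-domain protein — a smooth
    ellipsoid of points would be nearly centrosymmetric and its AFM
    image would barely constrain the orientation, which no real fitting
    target is.  The random clump layout also breaks all symmetry, so
    OBB grounding and orientation recovery are well-posed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    ext = np.asarray(extent, dtype=float)
    if n_atoms == 1:
        return AtomicModel(np.zeros((1, 3)), [radius])
    n_dom = max(1, min(n_domains, n_atoms))
    u = rng.normal(size=(n_dom, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    centers = u * rng.uniform(0.0, 1.0, size=(n_dom, 1)) ** (1.0 / 3.0)
    centers *= ext / 2.0
    which = rng.integers(0, n_dom, size=n_atoms)
    pts = centers[which] + rng.normal(scale=domain_sd, size=(n_atoms, 3))
    span = pts.max(axis=0) - pts.min(axis=0)
    span[span == 0] = 1.0
    pts *= ext / span
    pts -= pts.mean(axis=0)
    return AtomicModel(pts, np.full(n_atoms, float(radius)))


def make_filament(
    monomer: AtomicModel,
    n_units: int,
    rise: float = 2.75,
    twist: float = -166.7,
    ground: bool = True,
) -> AtomicModel:
    """Helical repetition of a monomer about Z: unit k is rotated by
    ``k * twist`` degrees and lifted by ``k * rise`` nm.

    The default rise/twist give an actin-like scale (synthetic; no
    structural fidelity claimed).  The result is OBB-grounded so the
    filament lies along the stage unless ``ground=False``.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    parts = []
    for k in range(n_units):
        rot = Rotation.from_euler("z", k * twist, degrees=True).as_matrix()
        parts.append(monomer.positions @ rot.T + np.array([0.0, 0.0, k * rise]))
    fil = AtomicModel(
        np.vstack(parts), np.tile(monomer.radii, n_units)
    )
    return ground_on_stage(fil) if ground else fil


@dataclass(frozen=True)
class GroundTruth:
    """What a twin experiment must recover: placement and probe shape."""

    quaternion: tuple[float, float, float, float]  # (x, y, z, w) of grounding
    translation: tuple[float, float, float]
    probe_radius: float
    probe_angle_deg: float
    seed: int
    noise_sd: float

    @property
    def probe(self) -> ProbeShape:
        return ProbeShape(self.probe_radius, self.probe_angle_deg)

    @property
    def transform(self) -> RigidTransform:
        rot = Rotation.from_quat(self.quaternion).as_matrix()
        return RigidTransform(rot, np.asarray(self.translation))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "quaternion_xyzw": list(self.quaternion),
                    "translation_nm": list(self.translation),
                    "probe_radius_nm": self.probe_radius,
                    "probe_angle_deg": self.probe_angle_deg,
                    "seed": self.seed,
                    "noise_sd_nm": self.noise_sd,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(d["quaternion_xyzw"]),
            tuple(d["translation_nm"]),
            d["probe_radius_nm"],
            d["probe_angle_deg"],
            d["seed"],
            d["noise_sd_nm"],
        )


def make_reference(
    model: AtomicModel,
    probe: ProbeShape,
    pixel: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    margin_px: int = 4,
) -> tuple[HeightMap, AtomicModel, GroundTruth]:
    """Grounded render of ``model`` embedded in a margin, plus noise.

    Returns ``(reference image, truth model in the reference frame,
    ground-truth record)``.  The margin leaves room for the translational
    search; with ``noise_sd=0`` the embedded pixels equal the plain
    render exactly.
    """
    grounded = ground_on_stage(model)
    tight = render(grounded, probe, pixel)
    ny, nx = tight.shape
    canvas = np.zeros((ny + 2 * margin_px, nx + 2 * margin_px))
    canvas[margin_px : margin_px + ny, margin_px : margin_px + nx] = tight.heights
    ref = HeightMap(canvas, pixel, (0.0, 0.0))
    # truth model expressed in the reference frame
    shift = np.array(
        [
            margin_px * pixel - tight.origin[0],
            margin_px * pixel - tight.origin[1],
            0.0,
        ]
    )
    truth_model = grounded.translated(shift)
    # net transform original -> reference frame
    rot, _ = _net_rotation(model, truth_model)
    trans = truth_model.centroid - rot @ model.centroid
    record = GroundTruth(
        tuple(Rotation.from_matrix(rot).as_quat().tolist()),
        tuple(trans.tolist()),
        probe.radius,
        probe.half_angle_deg,
        seed,
        noise_sd,
    )
    if noise_sd > 0:
        ref = add_noise(ref, noise_sd, seed)
    return ref, truth_model, record


def _net_rotation(a: AtomicModel, b: AtomicModel) -> tuple[np.ndarray, float]:
    """Rotation matrix carrying centered coords of ``a`` onto ``b`` (Kabsch)."""
    pa = a.positions - a.centroid
    pb = b.positions - b.centroid
    h = pa.T @ pb
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    rmsd = float(np.sqrt(np.mean(np.sum((pa @ rot.T - pb) ** 2, axis=1))))
    return rot, rmsd


def random_axis_rotation(seed: int) -> np.ndarray:
    """Random rotation built from uniform spins about X, Y and Z in turn.

    This is how a twin-experiment template is scrambled so the exact
    reference orientation is not on the search grid.
    """
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 360.0, size=3)
    return Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
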