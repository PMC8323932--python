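"""Pseudo-AFM image generation with a hemisphere + cone-frustum probe.

The probe tip is a hemisphere of radius ``r`` capped onto a circular cone
frustum whose side makes the half-apex angle ``theta`` with the vertical;
the frustum is treated as extending upward indefinitely (specimen heights
never reach a realistic frustum top).  For each pixel the probe descends
along the vertical through the pixel centre until it touches any atom
sphere; the apex height at first contact is the pixel value.  Pixels that
touch nothing read 0 (the stage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import FormatError
from .structure import AtomicModel


@dataclass(frozen=True)
class ProbeShape:
    """Probe-tip geometry: hemisphere radius (nm) and cone half-apex angle (deg)."""

    radius: float
    half_angle_deg: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("probe radius must be positive")
        if not 0 < self.half_angle_deg < 90:
            raise ValueError("half-apex angle must be in (0, 90) degrees")

    @property
    def half_angle_rad(self) -> float:
        return float(np.deg2rad(self.half_angle_deg))


@dataclass(frozen=True)
class HeightMap:
    """A rectangular grid of surface heights (nm).

    ``origin`` is the world coordinate (nm) of the lower-left corner of
    pixel (0, 0); pixel (i, j) has its centre at
    ``origin + ((j + 0.5), (i + 0.5)) * pixel_size`` with row 0 the lowest Y.
    """

    heights: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.shape[1]) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.shape[0]) + 0.5) * self.pixel_size

    def with_heights(self, heights: np.ndarray) -> "HeightMap":
        return replace(self, heights=np.asarray(heights, dtype=float))


def tip_height_over_atom(
    probe: ProbeShape, atom_z, atom_radius, lateral_distance
) -> np.ndarray:
    """Apex height at which the descending tip first touches an atom sphere.

    Two contact regimes, continuous at ``d = (r + r_a) cos(theta)``:

    * hemisphere contact (small lateral distance ``d``):
      ``z_tip = atom_z + sqrt((r + r_a)^2 - d^2) - r``
    * cone-flank contact (larger ``d``):
      ``z_tip = atom_z + (r + r_a - d cos(theta)) / sin(theta) - r``

    Accepts scalars or broadcastable arrays; the result can be negative
    for distant atoms (the rendered image floors pixel heights at the
    stage, z = 0).
    """
    d = np.asarray(lateral_distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("lateral distance must be non-negative")
    z_a = np.asarray(atom_z, dtype=float)
    r_a = np.asarray(atom_radius, dtype=float)
    r = probe.radius
    theta = probe.half_angle_rad
    big_r = r + r_a
    sphere = d <= big_r * np.cos(theta)
    with np.errstate(invalid="ignore"):
        z_sphere = z_a + np.sqrt(np.maximum(big_r**2 - d**2, 0.0)) - r
    z_cone = z_a + (big_r - d * np.cos(theta)) / np.sin(theta) - r
    return np.where(sphere, z_sphere, z_cone)


def probe_reach(probe: ProbeShape, atom_z: np.ndarray, atom_radius: np.ndarray) -> np.ndarray:
    """Largest lateral distance at which an atom still lifts the tip above z=0."""
    r, theta = probe.radius, probe.half_angle_rad
    big_r = np.asarray(atom_radius, float) + r
    # cone regime at z_tip = 0, plus the hemisphere bound as a safety margin
    cone = (big_r + (np.asarray(atom_z, float) - r) * np.sin(theta)) / np.cos(theta)
    return np.maximum(cone, big_r)


def auto_frame(
    model: AtomicModel, probe: ProbeShape, pixel_size: float, pad_px: int = 0
) -> tuple[tuple[float, float], tuple[int, int]]:
    """Tight frame (origin, (ny, nx)) covering every pixel the tip can feel.

    The origin snaps to integer multiples of the pixel size so that images
    of models translated by whole pixels are shifted copies of each other.
    """
    reach = probe_reach(probe, model.positions[:, 2], model.radii)
    x = model.positions[:, 0]
    y = model.positions[:, 1]
    x0 = np.floor((x - reach).min() / pixel_size) - pad_px
    y0 = np.floor((y - reach).min() / pixel_size) - pad_px
    x1 = np.ceil((x + reach).max() / pixel_size) + pad_px
    y1 = np.ceil((y + reach).max() / pixel_size) + pad_px
    nx = int(x1 - x0)
    ny = int(y1 - y0)
    return (float(x0 * pixel_size), float(y0 * pixel_size)), (ny, nx)


def render(
    model: AtomicModel,
    probe: ProbeShape,
    pixel_size: float,
    frame: tuple[tuple[float, float], tuple[int, int]] | None = None,
    _chunk: int = 4_000_000,
) -> HeightMap:
    """Render a pseudo-AFM height map of ``model`` seen through ``probe``.

    Each pixel value is ``max(0, max over atoms of tip_height_over_atom)``
    evaluated at the pixel centre.  ``frame`` is ``(origin, (ny, nx))``;
    when omitted a tight frame covering the model's footprint is used.
    """
    if not pixel_size > 0:
        raise ValueError("pixel size must be positive")
    if len(model) == 0:
        if frame is None:
            raise ValueError("cannot auto-frame an empty model")
        origin, (ny, nx) = frame
        return HeightMap(np.zeros((ny, nx)), pixel_size, origin)
    if frame is None:
        frame = auto_frame(model, probe, pixel_size)
    origin, (ny, nx) = frame
    hmap = HeightMap(np.zeros((ny, nx)), pixel_size, origin)
    xc = hmap.x_centers()
    yc = hmap.y_centers()

    pos = model.positions
    rad = model.radii
    heights = np.zeros((ny, nx))
    # chunk atoms to bound the (ny, nx, natoms) intermediate
    n_chunk = max(1, _chunk // max(ny * nx, 1))
    for start in range(0, len(model), n_chunk):
        p = pos[start : start + n_chunk]
        r_a = rad[start : start + n_chunk]
        dx = xc[None, :, None] - p[None, None, :, 0]
        dy = yc[:, None, None] - p[None, None, :, 1]
        d = np.sqrt(dx * dx + dy * dy)  # (ny, nx, n)
        z = tip_height_over_atom(probe, p[:, 2], r_a, d)
        np.maximum(heights, z.max(axis=2), out=heights)
    np.maximum(heights, 0.0, out=heights)
    return hmap.with_heights(heights)


def add_noise(img: HeightMap, sigma: float, seed: int) -> HeightMap:
    """Add spatially independent Gaussian noise (mean 0, sd ``sigma`` nm).

    Heights are deliberately not clipped at zero: background noise in
    experimental images is symmetric about the stage plane.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return img
    rng = np.random.default_rng(seed)
    return img.with_heights(img.heights + rng.normal(0.0, sigma, img.shape))


# ---------------------------------------------------------------------------
# plain-text height-map format


def write_heightmap(img: HeightMap, path) -> None:
    """Write a height map as a tab-separated text matrix with header comments."""
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_nm={img.pixel_size:.6g}\n")
        fh.write(f"# origin_nm={img.origin[0]:.6g},{img.origin[1]:.6g}\n")
        for row in img.heights:
            fh.write("\t".join(f"{v:.4f}" for v in row) + "\n")


def read_heightmap(path) -> HeightMap:
    """Read a height map written by :func:`write_heightmap`.

    Values may be separated by tabs or commas; ``#`` lines may carry
    ``pixel_size_nm`` and ``origin_nm`` headers (defaults 1.0 and (0, 0)).
    """
    pixel_size = 1.0
    origin = (0.0, 0.0)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("pixel_size_nm="):
                    pixel_size = float(body.split("=", 1)[1])
                elif body.startswith("origin_nm="):
                    parts = body.split("=", 1)[1].replace(",", " ").split()
                    origin = (float(parts[0]), float(parts[1]))
                continue
            vals = line.replace(",", "\t").split()
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise FormatError(f"bad height-map line {line!r}") from exc
    if not rows:
        raise FormatError(f"no data rows in {path}")
    if len({len(r) for r in rows}) != 1:
        raise FormatError("ragged height-map rows")
    return HeightMap(np.array(rows), pixel_size, origin)
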