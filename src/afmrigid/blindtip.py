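"""Blind tip reconstruction from a height map (morphological outer bound).

An AFM image is the greyscale dilation of the true surface by the
(reflected) tip, so the image itself constrains how sharp the tip can
be.  Writing ``P(d) <= 0`` for the reflected tip profile relative to its
apex (``P(0) = 0``), two facts hold for every image pixel ``y``:

* somewhere inside the tip window there is a contact point ``u`` with
  surface height ``S(u) = i(y) - P(y - u) >= i(y)``, and any such ``u``
  must satisfy ``i(u) >= i(y) - P(y - u)`` (the image bounds the surface
  from above);
* for every pixel ``x``, ``i(x) >= S(u) + P(x - u)``.

Combining them: for every ``y`` and offset ``d``,
``P(d) <= max_u [ i(u + d) ] - i(y)`` where ``u`` runs over the feasible
contact set ``U(y) = { u : y - u in window, i(u) >= i(y) - P(y - u) }``
built from the current estimate.  Starting from the bluntest tip
(``P = 0``, a flat plane) and iterating this update to a fixed point
yields a monotonically sharpening estimate that never becomes sharper
than the true tip (the classic blind-reconstruction outer bound).  A
noise ``threshold`` tau relaxes both the feasibility test and the bound,
trading sharpness for robustness.

The tip is stored as a depth map ``t = -P >= 0`` (0 at the apex,
growing outward), on the same pixel grid as the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imaging import HeightMap


@dataclass(frozen=True)
class TipSurface:
    """Reflected-tip profile on an odd square window, as depth below apex (nm).

    The apex sits at the window centre with value 0; values grow outward
    (a blunt tip grows slowly).  ``pixel_size`` matches the source image.
    """

    profile: np.ndarray
    pixel_size: float

    def __post_init__(self):
        p = np.asarray(self.profile, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] % 2 != 1:
            raise ValueError("tip profile must be an odd square array")
        if np.any(p < 0):
            raise ValueError("tip depths must be non-negative")
        k = p.shape[0] // 2
        if p[k, k] != 0:
            raise ValueError("apex depth must be 0")
        object.__setattr__(self, "profile", p)

    @property
    def half_width(self) -> int:
        return self.profile.shape[0] // 2

    def cross_sections(self) -> tuple[np.ndarray, np.ndarray]:
        """Depth profiles along X and Y through the apex."""
        k = self.half_width
        return self.profile[k, :].copy(), self.profile[:, k].copy()

    def apex_radius(self) -> float:
        """Curvature radius at the apex from the nearest-neighbour rise.

        A parabolic apex of curvature radius R rises ``d^2 / (2 R)`` at
        lateral distance ``d``; R is estimated from the four axial
        neighbours of the apex (``inf`` for a locally flat estimate).
        """
        k = self.half_width
        if k == 0:
            return float("inf")
        rise = float(np.mean([
            self.profile[k, k - 1], self.profile[k, k + 1],
            self.profile[k - 1, k], self.profile[k + 1, k],
        ]))
        if rise <= 0:
            return float("inf")
        return self.pixel_size**2 / (2.0 * rise)


def probe_tip_surface(probe, pixel_size: float, half_width: int) -> TipSurface:
    """Sample a hemisphere + cone probe as a :class:`TipSurface` depth map."""
    k = half_width
    xs = (np.arange(-k, k + 1)) * pixel_size
    d = np.hypot(xs[:, None], xs[None, :])
    r, theta = probe.radius, probe.half_angle_rad
    rho_j = r * np.cos(theta)
    depth = np.where(
        d <= rho_j,
        r - np.sqrt(np.maximum(r * r - d * d, 0.0)),
        r * (1.0 - np.sin(theta)) + (d - rho_j) / np.tan(theta),
    )
    depth[k, k] = 0.0
    return TipSurface(depth, pixel_size)


def erode_by_tip(img: HeightMap, tip: TipSurface) -> HeightMap:
    """Surface reconstruction ``I erosion P``: ``min_d [ i(x + d) + t(d) ]``.

    The image is continued by +inf outside its frame (no constraint).
    """
    k = tip.half_width
    padded = np.pad(img.heights, k, constant_values=np.inf)
    out = np.full(img.shape, np.inf)
    for di in range(-k, k + 1):
        for dj in range(-k, k + 1):
            shifted = padded[k + di : k + di + img.shape[0],
                             k + dj : k + dj + img.shape[1]]
            np.minimum(out, shifted + tip.profile[k + di, k + dj], out=out)
    return img.with_heights(out)


def dilate_by_tip(surface: HeightMap, tip: TipSurface) -> HeightMap:
    """Image simulation ``S dilation P``: ``max_d [ s(x - d) - t(d) ]``.

    Adjoint of :func:`erode_by_tip`, so eroding then dilating (a
    morphological opening) never exceeds the original image.
    """
    k = tip.half_width
    padded = np.pad(surface.heights, k, constant_values=-np.inf)
    out = np.full(surface.shape, -np.inf)
    for di in range(-k, k + 1):
        for dj in range(-k, k + 1):
            shifted = padded[k - di : k - di + surface.shape[0],
                             k - dj : k - dj + surface.shape[1]]
            np.maximum(out, shifted - tip.profile[k + di, k + dj], out=out)
    return surface.with_heights(out)


def blind_tip_estimate(
    img: HeightMap,
    tip_window: int = 11,
    threshold: float = 0.0,
    max_iter: int = 20,
    tol: float = 1e-10,
) -> TipSurface:
    """Estimate an outer bound on the tip shape directly from an image.

    Parameters
    ----------
    tip_window:
        Odd side length (pixels) of the tip support to reconstruct.  The
        image must be at least ``2 * tip_window - 1`` pixels on each side
        so that interior pixels see a full double window.
    threshold:
        Noise tolerance in nm: each refinement is weakened by this
        amount, so pixel noise does not force an unphysically sharp tip.
        The estimate blunts monotonically as the threshold grows.
    max_iter:
        Iteration cap; the fixed point is normally reached in a few
        passes.
    """
    if tip_window % 2 != 1 or tip_window < 3:
        raise ValueError("tip_window must be odd and >= 3")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    k = tip_window // 2
    if 4 * k + 1 > min(img.shape):
        raise ValueError(
            f"tip window {tip_window} too large for a {img.shape} image"
        )
    i_arr = img.heights
    nrow, ncol = img.shape
    w = tip_window
    # double windows around every interior pixel y: patches[y][a, b] =
    # i(y + (a - 2k, b - 2k)), so patches index both u = y + delta and u + d
    patches = sliding_window_view(i_arr, (4 * k + 1, 4 * k + 1))
    n_int_r, n_int_c = patches.shape[:2]
    depth = np.zeros((w, w))
    for _ in range(max_iter):
        prev = depth
        new = depth.copy()
        # max_u i(u + d) with u feasible, evaluated per interior pixel
        for yi in range(n_int_r):
            row_patches = patches[yi]  # (n_int_c, 4k+1, 4k+1)
            centers = row_patches[:, 2 * k, 2 * k]  # i(y)
            # A[y][a, b, c, d] = i(y + delta_{a,b} + d_{c,d})
            a_view = sliding_window_view(row_patches, (w, w), axis=(1, 2))
            # feasibility: i(y + delta) >= i(y) + t(-delta) - threshold
            inner = row_patches[:, k : 3 * k + 1, k : 3 * k + 1]  # i(y + delta)
            feas = inner >= (
                centers[:, None, None] + prev[::-1, ::-1][None, :, :] - threshold
            )
            masked = np.where(feas[:, :, :, None, None], a_view, -np.inf)
            reach = masked.max(axis=(1, 2))  # (n_int_c, w, w)
            cand = (centers[:, None, None] - reach - threshold).max(axis=0)
            np.maximum(new, cand, out=new)
        new = np.maximum(new, 0.0)
        new[k, k] = 0.0
        if np.max(np.abs(new - depth)) <= tol:
            depth = new
            break
        depth = new
    return TipSurface(depth, img.pixel_size)
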