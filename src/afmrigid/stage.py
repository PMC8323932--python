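"""Stage-plane estimation, background flattening and noise statistics.

Experimental AFM stages are close to, but never exactly, horizontal.
Before fitting, the stage is modelled as a tilted plane
``z = a x + b y + c`` fitted by ordinary least squares over background
pixels, subtracted from the image, and the residual spread gives the
per-pixel noise level.  A small affine rescaling utility supports
post-hoc comparison of best-fit images against a reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .imaging import HeightMap


@dataclass(frozen=True)
class PlaneFit:
    """Fitted stage plane ``z = a x + b y + c`` (x, y, z in nm)."""

    a: float
    b: float
    c: float
    residual_sd: float

    def evaluate(self, img: HeightMap) -> np.ndarray:
        """Plane heights at every pixel centre of ``img``."""
        x = img.x_centers()[None, :]
        y = img.y_centers()[:, None]
        return self.a * x + self.b * y + self.c


def mask_from_rects(img: HeightMap, rects) -> np.ndarray:
    """Boolean mask from ``(row0, row1, col0, col1)`` half-open rectangles."""
    mask = np.zeros(img.shape, dtype=bool)
    for r0, r1, c0, c1 in rects:
        mask[r0:r1, c0:c1] = True
    return mask

def mask_below_quantile(img: HeightMap, quantile: float = 0.25) -> np.ndarray:
    """Automatic background mask: pixels at or below a height quantile."""
    return img.heights <= np.quantile(img.heights, quantile)


def _masked_design(img: HeightMap, mask: np.ndarray | None):
    if mask is None:
        mask = mask_below_quantile(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape does not match image")
    ys, xs = np.nonzero(mask)
    if len(xs) < 3:
        raise DegenerateGeometryError("need at least 3 background pixels")
    x = img.x_centers()[xs]
    y = img.y_centers()[ys]
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateGeometryError("background pixels are coincident")
    design = np.column_stack([x, y, np.ones_like(x)])
    z = img.heights[ys, xs]
    return design, z


def fit_stage_plane(img: HeightMap, mask: np.ndarray | None = None) -> PlaneFit:
    """Least-squares tilted-plane fit of the stage over background pixels.

    ``mask`` selects background pixels; by default the lowest height
    quartile stands in for a manual selection.  Raises on degenerate
    (collinear) masks, where the plane is not identifiable.
    """
    design, z = _masked_design(img, mask)
    coef, _, rank, _ = np.linalg.lstsq(design, z, rcond=None)
    if rank < 3:
        raise DegenerateGeometryError("background pixels are collinear")
    resid = z - design @ coef
    dof = max(len(z) - 3, 1)
    sd = float(np.sqrt(np.sum(resid * resid) / dof))
    return PlaneFit(float(coef[0]), float(coef[1]), float(coef[2]), sd)


def subtract_plane(img: HeightMap, fit: PlaneFit) -> HeightMap:
    """Subtract the fitted stage plane; heights are not clipped at zero."""
    return img.with_heights(img.heights - fit.evaluate(img))


def noise_sd(img: HeightMap, mask: np.ndarray | None = None) -> float:
    """Background noise level: sd of residuals about the fitted stage plane."""
    return fit_stage_plane(img, mask).residual_sd


def noise_histogram(
    img: HeightMap, mask: np.ndarray | None = None, bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin edges) of plane residuals over the mask."""
    if mask is None:
        mask = mask_below_quantile(img)
    fit = fit_stage_plane(img, mask)
    resid = (img.heights - fit.evaluate(img))[np.asarray(mask, bool)]
    return np.histogram(resid, bins=bins)


def affine_rescale(
    img: HeightMap,
    ref: HeightMap,
    mode: str = "both",
    nonpositive_shift: bool = False,
) -> tuple[float, float, HeightMap]:
    """Least-squares uniform scale/shift of ``img`` onto ``ref``.

    Finds ``(s, t)`` minimizing ``sum((s * H + t - H_ref)^2)`` and returns
    them with the rescaled image.  ``mode`` is ``"scale"`` (t = 0),
    ``"shift"`` (s = 1) or ``"both"``; ``nonpositive_shift`` constrains
    t <= 0 (useful when the physical shift can only lower the image).
    """
    if img.shape != ref.shape:
        raise ValueError("images must have the same shape")
    h = img.heights.ravel()
    r = ref.heights.ravel()
    if mode == "shift":
        s, t = 1.0, float(np.mean(r - h))
    elif mode == "scale":
        denom = float(np.dot(h, h))
        if denom == 0:
            raise ValueError("zero-variance image in scale mode")
        s, t = float(np.dot(h, r) / denom), 0.0
    elif mode == "both":
        var = float(np.var(h))
        if var == 0:
            raise ValueError("zero-variance image in scale mode")
        s = float(np.cov(h, r, bias=True)[0, 1] / var)
        t = float(np.mean(r) - s * np.mean(h))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if nonpositive_shift and t > 0:
        # KKT: the constrained optimum sits on the boundary t = 0
        t = 0.0
        if mode in ("both", "scale"):
            denom = float(np.dot(h, h))
            if denom == 0:
                raise ValueError("zero-variance image in scale mode")
            s = float(np.dot(h, r) / denom)
        else:
            s = 1.0
    return s, t, img.with_heights(s * img.heights + t)
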