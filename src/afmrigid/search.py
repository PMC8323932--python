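"""Exhaustive rigid-body search over orientation, translation, height and probe.

The search discretizes every degree of freedom and scans the full product
grid, exactly as the method's design intends: no stochastic optimizer and
no FFT shortcut, so the global optimum on the grid is found by
construction.  Degrees of freedom:

* orientation — near-uniform directions on the sphere (latitude rings
  populated proportionally to ring index) combined with spins about the
  new Z axis, both at the same angular step;
* XY translation — integer pixel offsets keeping the trimmed pseudo-image
  window inside the reference;
* Z offset — multiples of a small step, searched only when the reference
  is taller than the pseudo-image;
* probe shape — an explicit list of (radius, half-angle) candidates.

Ties are broken deterministically in enumeration order: orientation
index, then row-major window offset, then Z index, then probe index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.transform import Rotation

from .errors import EmptySimImageError, SearchError
from .imaging import HeightMap, ProbeShape, render
from .scores import SCORE_NAMES, PenaltyParams, nonzero_bbox
from .structure import AtomicModel, RigidTransform

log = logging.getLogger(__name__)

#: Probe grids used by default: radii spanning the range of real AFM tips
#: (six values from 0.5 to 5 nm) and half-apex angles from 5 to 30 degrees.
DEFAULT_PROBE_RADII = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_PROBE_ANGLES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

#: Default Z search step in nm, finer than the vertical resolution of
#: typical high-speed AFM instruments (0.05-0.15 nm).
DEFAULT_Z_STEP = 0.064


def default_probe_grid(
    radii: Sequence[float] = DEFAULT_PROBE_RADII,
    angles: Sequence[float] = DEFAULT_PROBE_ANGLES,
) -> list[ProbeShape]:
    """All combinations of the given radii (nm) and half-apex angles (deg)."""
    return [ProbeShape(r, a) for r in radii for a in angles]


def _validate_step(step: float) -> int:
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ValueError(f"step {step} must divide 360 degrees")
    n = int(round(360.0 / step))
    if n % 4 != 0:
        raise ValueError(f"360/step must be a multiple of 4, got {n}")
    return n


def sphere_directions(step: float, ring_multiplier: int = 4) -> np.ndarray:
    """Near-uniform direction vectors on the unit sphere.

    Latitude rings sit at polar angles ``n * step`` from the +Z pole; ring
    ``n`` carries ``ring_multiplier * n`` evenly spaced azimuths (the
    poles carry one point each).  With the default multiplier of 4 the
    equator ring is divided at exactly the angular step, which keeps the
    nearest-neighbour spacing close to ``step`` everywhere.
    """
    _validate_step(step)
    if ring_multiplier < 1:
        raise ValueError("ring_multiplier must be >= 1")
    n_rings = int(round(180.0 / step))
    dirs = []
    for n in range(n_rings + 1):
        phi = np.deg2rad(n * step)
        if n == 0 or n == n_rings:
            azimuths = [0.0]
        else:
            m = max(ring_multiplier * n, 1)
            azimuths = [2.0 * np.pi * j / m for j in range(m)]
        for lam in azimuths:
            dirs.append(
                (np.sin(phi) * np.cos(lam), np.sin(phi) * np.sin(lam), np.cos(phi))
            )
    return np.array(dirs)


def orientation_angles(step: float, ring_multiplier: int = 4) -> np.ndarray:
    """ZYZ Euler angle triplets (degrees) of the full orientation grid.

    For each sphere direction (polar ``phi``, azimuth ``lam``) the molecule
    is rotated so +Z maps onto the direction, then spun about the new Z
    axis in increments of ``step``; the triplet is ``(lam, phi, psi)``.
    """
    _validate_step(step)
    n_spins = int(round(360.0 / step))
    n_rings = int(round(180.0 / step))
    out = []
    for n in range(n_rings + 1):
        phi = n * step
        if n == 0 or n == n_rings:
            azimuths = [0.0]
        else:
            m = max(ring_multiplier * n, 1)
            azimuths = [360.0 * j / m for j in range(m)]
        for lam in azimuths:
            for k in range(n_spins):
                out.append((lam, phi, k * step))
    return np.array(out)


def orientations(step: float, ring_multiplier: int = 4) -> np.ndarray:
    """Rotation matrices of the orientation grid, shape (n, 3, 3)."""
    angles = orientation_angles(step, ring_multiplier)
    return Rotation.from_euler("ZYZ", angles, degrees=True).as_matrix()


def translation_grid(sim: HeightMap, ref: HeightMap) -> list[tuple[int, int]]:
    """Integer pixel placements of the trimmed sim window inside the reference.

    Each entry ``(row, col)`` is the reference pixel under the window's
    lower corner; offsets are enumerated row-major.  An oversized window
    yields an empty list with a warning.
    """
    r0, r1, c0, c1 = nonzero_bbox(sim.heights)
    h, w = r1 - r0, c1 - c0
    nrow, ncol = ref.heights.shape
    if h > nrow or w > ncol:
        log.warning("sim window %dx%d exceeds reference %dx%d", h, w, nrow, ncol)
        return []
    return [(r, c) for r in range(nrow - h + 1) for c in range(ncol - w + 1)]


def z_offsets(sim: HeightMap, ref: HeightMap, step: float = DEFAULT_Z_STEP) -> np.ndarray:
    """Vertical shifts to scan: multiples of ``step`` up to the height gap.

    Only when the reference contains a pixel taller than every pixel of
    the pseudo-image is a lift worth trying; otherwise just ``[0]``.
    """
    return _z_offset_values(float(sim.heights.max()), float(ref.heights.max()), step)


def _z_offset_values(sim_max: float, ref_max: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("z step must be positive")
    gap = ref_max - sim_max
    if gap <= 0:
        return np.array([0.0])
    k = int(np.floor(gap / step))
    return step * np.arange(k + 1)


@dataclass(frozen=True)
class SearchResult:
    """One scored candidate placement of the model.

    ``transform`` maps the input model's coordinates into the reference
    frame (rotation about the model centroid, then grounding and the XY
    placement); ``z_offset`` is the extra vertical lift applied to the
    rendered image (and to the placed structure when evaluating it).
    """

    transform: RigidTransform
    z_offset: float
    probe: ProbeShape
    cost: float
    score_name: str
    offset_px: tuple[int, int]
    orientation_index: int
    probe_index: int
    z_index: int

    def place(self, model: AtomicModel) -> AtomicModel:
        """Return the model at this candidate's placement (z lift included)."""
        placed = model.transformed(self.transform)
        return placed.translated((0.0, 0.0, self.z_offset))


@dataclass(frozen=True)
class SearchOutcome:
    """Full result of one exhaustive search for one score."""

    score_name: str
    ranked: list  # top-k SearchResult, best first
    per_probe: list  # best SearchResult per probe (None where undefined)

    @property
    def best(self) -> SearchResult:
        return self.ranked[0]


def _rotate_ground(model: AtomicModel, rot: np.ndarray) -> np.ndarray:
    """Rotate about the centroid and rest on the stage; returns positions."""
    pos = (model.positions - model.centroid) @ rot.T
    pos[:, 2] -= np.min(pos[:, 2] - model.radii)
    return pos


def _window_costs(
    window: np.ndarray,
    ref_arr: np.ndarray,
    z_values: np.ndarray,
    score_names: Sequence[str],
    pp: PenaltyParams,
) -> dict[str, np.ndarray]:
    """Costs of one trimmed sim window at every (row, col, z) placement.

    Returns arrays of shape (n_rows, n_cols, n_z); undefined scores are
    ``inf``.  Sums over sliding reference windows are computed directly
    (no FFT) via stride tricks.
    """
    h, w = window.shape
    sw = sliding_window_view(ref_arr, (h, w))  # (nr, nc, h, w) view
    nr, nc = sw.shape[:2]
    n = h * w
    need_moments = any(s in score_names for s in ("cosine", "correlation", "pixel_rmsd"))
    if need_moments:
        ref_sum = np.einsum("ijkl->ij", sw)
        ref_sq = np.einsum("ijkl,ijkl->ij", sw, sw)
    support = window > 0
    out = {s: np.empty((nr, nc, len(z_values))) for s in score_names}
    for zi, lift in enumerate(z_values):
        ws = window + lift * support
        if need_moments:
            dot = np.einsum("ijkl,kl->ij", sw, ws)
            s_sum = ws.sum()
            s_sq = float(np.dot(ws.ravel(), ws.ravel()))
        for name in score_names:
            if name == "cosine":
                denom = np.sqrt(ref_sq * s_sq)
                with np.errstate(divide="ignore", invalid="ignore"):
                    cost = 1.0 - dot / denom
                cost[denom == 0] = np.inf
            elif name == "correlation":
                cov = dot - ref_sum * (s_sum / n)
                var_r = ref_sq - ref_sum * ref_sum / n
                var_s = s_sq - s_sum * s_sum / n
                denom = np.sqrt(np.maximum(var_r, 0.0) * max(var_s, 0.0))
                with np.errstate(divide="ignore", invalid="ignore"):
                    cost = 1.0 - cov / denom
                cost[denom <= 0] = np.inf
            elif name == "pixel_rmsd":
                cost = np.sqrt(np.maximum(ref_sq - 2.0 * dot + s_sq, 0.0) / n)
            elif name == "penalty":
                over = sw < ws  # ref strictly below sim: forbidden
                reward = ~over & (sw < ws + pp.thickness)
                cost = pp.k_penalty * np.einsum(
                    "ijkl->ij", over, dtype=np.int64
                ) - pp.k_reward * np.einsum("ijkl->ij", reward, dtype=np.int64)
                cost = cost.astype(float)
            else:
                raise ValueError(f"unknown score {name!r}")
            out[name][:, :, zi] = cost
    return out


class _TopK:
    """Running top-k candidate list ordered by (cost, enumeration key)."""

    def __init__(self, k: int):
        self.k = k
        self.items: list[tuple] = []

    def extend(self, candidates):
        self.items.extend(candidates)
        self.items.sort()
        del self.items[self.k :]


def exhaustive_search_multi(
    model: AtomicModel,
    ref: HeightMap,
    probes: Sequence[ProbeShape] | None = None,
    score_names: Sequence[str] = ("cosine",),
    step: float = 10.0,
    z_step: float = DEFAULT_Z_STEP,
    top_k: int = 10,
    ring_multiplier: int = 4,
    penalty_params: PenaltyParams | None = None,
    progress: bool = False,
) -> dict[str, SearchOutcome]:
    """Scan the full grid once, scoring every candidate under every score.

    Rendering a pseudo-image depends only on orientation and probe, so all
    requested scores share one pass over the renders; this is how the twin
    harness compares scores without multiplying the runtime.
    """
    probes = list(probes) if probes is not None else default_probe_grid()
    for s in score_names:
        if s not in SCORE_NAMES:
            raise ValueError(f"unknown score {s!r}")
    pp = penalty_params or PenaltyParams()
    rots = orientations(step, ring_multiplier)
    if len(rots) == 0 or len(probes) == 0:
        raise SearchError("empty orientation or probe grid")
    if ref.heights.size == 0:
        raise SearchError("empty reference image")

    best = {s: _TopK(top_k) for s in score_names}
    per_probe: dict[str, list] = {s: [None] * len(probes) for s in score_names}
    n_evaluated = 0
    for o_idx, rot in enumerate(rots):
        pos = _rotate_ground(model, rot)
        m_rot = replace(model, positions=pos)
        for p_idx, probe in enumerate(probes):
            sim = render(m_rot, probe, ref.pixel_size)
            try:
                r0, r1, c0, c1 = nonzero_bbox(sim.heights)
            except EmptySimImageError:
                continue
            window = sim.heights[r0:r1, c0:c1]
            h, w = window.shape
            nrow, ncol = ref.heights.shape
            if h > nrow or w > ncol:
                log.warning(
                    "orientation %d probe %d: window %dx%d exceeds reference",
                    o_idx, p_idx, h, w,
                )
                continue
            zvals = _z_offset_values(
                float(window.max()), float(ref.heights.max()), z_step
            )
            costs = _window_costs(window, ref.heights, zvals, score_names, pp)
            n_evaluated += costs[score_names[0]].size
            for name in score_names:
                arr = costs[name]  # (nr, nc, nz): ravel order matches tie key
                flat = arr.ravel()
                k = min(top_k, flat.size)
                # stable sort so equal costs keep (row, col, z) enumeration order
                idx = np.argsort(flat, kind="stable")[:k]
                cands = []
                for ii in idx:
                    rr, cc, zi = np.unravel_index(ii, arr.shape)
                    cands.append(
                        (float(flat[ii]), o_idx, int(rr), int(cc), int(zi), p_idx,
                         float(zvals[zi]))
                    )
                best[name].extend(cands)
                if cands:
                    top = cands[0]
                    cur = per_probe[name][p_idx]
                    if cur is None or top < cur:
                        per_probe[name][p_idx] = top
        if progress and o_idx % 50 == 0:
            log.info("orientation %d/%d", o_idx + 1, len(rots))
    log.info("evaluated %d candidates over %d orientations", n_evaluated, len(rots))

    out = {}
    for name in score_names:
        ranked = [
            _build_result(model, ref, rots, probes, cand, name)
            for cand in best[name].items
        ]
        if not ranked:
            raise SearchError("no candidate could be evaluated")
        pp_results = [
            None if c is None else _build_result(model, ref, rots, probes, c, name)
            for c in per_probe[name]
        ]
        out[name] = SearchOutcome(name, ranked, pp_results)
    return out


def _build_result(
    model: AtomicModel,
    ref: HeightMap,
    rots: np.ndarray,
    probes: Sequence[ProbeShape],
    cand: tuple,
    score_name: str,
) -> SearchResult:
    """Reconstruct the rigid transform for a winning candidate tuple."""
    cost, o_idx, rr, cc, zi, p_idx, z_val = cand
    rot = rots[o_idx]
    pos = _rotate_ground(model, rot)
    m_rot = replace(model, positions=pos)
    probe = probes[p_idx]
    sim = render(m_rot, probe, ref.pixel_size)
    r0, r1, c0, c1 = nonzero_bbox(sim.heights)
    px = ref.pixel_size
    t_x = ref.origin[0] - sim.origin[0] + (cc - c0) * px
    t_y = ref.origin[1] - sim.origin[1] + (rr - r0) * px
    # full transform: rotate about centroid, ground, then place in ref frame
    dz = pos[0, 2] - (rot @ (model.positions[0] - model.centroid))[2]
    translation = -rot @ model.centroid + np.array([t_x, t_y, dz])
    return SearchResult(
        transform=RigidTransform(rot, translation),
        z_offset=float(z_val),
        probe=probe,
        cost=float(cost),
        score_name=score_name,
        offset_px=(int(rr), int(cc)),
        orientation_index=int(o_idx),
        probe_index=int(p_idx),
        z_index=int(zi),
    )


def exhaustive_fit(
    model: AtomicModel,
    ref: HeightMap,
    probes: Sequence[ProbeShape] | None = None,
    score_name: str = "cosine",
    step: float = 10.0,
    z_step: float = DEFAULT_Z_STEP,
    top_k: int = 10,
    ring_multiplier: int = 4,
    penalty_params: PenaltyParams | None = None,
) -> list[SearchResult]:
    """Exhaustive fit under one score; returns the top-k candidates, best first."""
    outcome = exhaustive_search_multi(
        model, ref, probes, (score_name,), step, z_step, top_k,
        ring_multiplier, penalty_params,
    )
    return outcome[score_name].ranked
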