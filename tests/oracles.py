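"""Independent brute-force oracles used by the test suite.

Each oracle avoids the code path it checks: the tip-contact oracle
descends a densely sampled tip surface instead of using the closed-form
contact heights; the render oracle loops pixels and atoms; the search
oracle enumerates the full grid with plain Python loops and the scalar
scoring functions.
"""

from __future__ import annotations

import numpy as np

from afmrigid.imaging import HeightMap, ProbeShape
from afmrigid.scores import PenaltyParams, TrimmedPair, nonzero_bbox, score_cost
from afmrigid.search import _rotate_ground, _z_offset_values, orientations
from afmrigid.structure import AtomicModel


def tip_surface_profile(probe: ProbeShape, rho: np.ndarray) -> np.ndarray:
    """Height of the tip surface above the apex at radial distance rho.

    Hemisphere of radius r up to the tangency circle rho = r cos(theta),
    then the cone flank of half-apex angle theta.
    """
    r, theta = probe.radius, probe.half_angle_rad
    rho_j = r * np.cos(theta)
    sphere = r - np.sqrt(np.maximum(r * r - np.minimum(rho, rho_j) ** 2, 0.0))
    cone = r * (1.0 - np.sin(theta)) + (rho - rho_j) / np.tan(theta)
    return np.where(rho <= rho_j, sphere, cone)


def descend_tip_to_contact(
    probe: ProbeShape,
    atom_z: float,
    atom_radius: float,
    lateral_distance: float,
    z_resolution: float = 1e-4,
    n_surface: int = 40001,
) -> float:
    """Apex height at first tip-atom contact, by descent over a sampled surface.

    The tip surface is sampled as a dense radial point cloud; the apex
    height is lowered (by bisection down to ``z_resolution``) until the
    minimum distance from the atom centre to the surface reaches the atom
    radius.  Purely geometric: shares no formula with the closed-form
    contact heights under test.
    """
    d = lateral_distance
    # surface samples only matter within atom reach of the atom's lateral
    # position; sample a generous radial range
    rho_max = d + 2.0 * (atom_radius + probe.radius) + 1.0
    rho = np.linspace(0.0, rho_max, n_surface)
    t = tip_surface_profile(probe, rho)

    t_at_d = tip_surface_profile(probe, np.array([d]))[0]

    def touches(apex_z: float) -> bool:
        # overlap if the atom centre is inside the tip solid, or within
        # the atom radius of the sampled tip surface
        if atom_z >= apex_z + t_at_d:
            return True
        dist2 = (rho - d) ** 2 + (apex_z + t - atom_z) ** 2
        return bool(np.min(dist2) <= atom_radius**2)

    # surely touching: the atom centre is inside the tip solid once the
    # apex is below atom_z - T(d)
    lo = atom_z - t_at_d - 1.0
    hi = atom_z + atom_radius + 1e-6  # surely clear (tip surface >= apex)
    assert touches(lo) and not touches(hi)
    while hi - lo > z_resolution:
        mid = 0.5 * (lo + hi)
        if touches(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def render_loop(model: AtomicModel, probe: ProbeShape, hmap: HeightMap) -> np.ndarray:
    """Per-pixel / per-atom double loop using the scalar contact height."""
    from afmrigid.imaging import tip_height_over_atom

    xs = hmap.x_centers()
    ys = hmap.y_centers()
    out = np.zeros(hmap.shape)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            best = 0.0
            for (ax, ay, az), r_a in zip(model.positions, model.radii):
                d = float(np.hypot(x - ax, y - ay))
                z = float(tip_height_over_atom(probe, az, r_a, d))
                best = max(best, z)
            out[i, j] = best
    return out


def naive_exhaustive_fit(
    model: AtomicModel,
    ref: HeightMap,
    probes,
    score_name: str,
    step: float,
    z_step: float,
    penalty_params: PenaltyParams | None = None,
):
    """Quadruple loop over orientation, offset, z and probe; returns the
    best candidate as (cost, o_idx, row, col, z_idx, p_idx) with ties
    broken in that enumeration order."""
    from afmrigid.imaging import render

    pp = penalty_params or PenaltyParams()
    rots = orientations(step)
    best = None
    for o_idx, rot in enumerate(rots):
        pos = _rotate_ground(model, rot)
        m_rot = AtomicModel(pos, model.radii)
        for p_idx, probe in enumerate(probes):
            sim = render(m_rot, probe, ref.pixel_size)
            try:
                r0, r1, c0, c1 = nonzero_bbox(sim.heights)
            except Exception:
                continue
            window = sim.heights[r0:r1, c0:c1]
            h, w = window.shape
            nrow, ncol = ref.heights.shape
            if h > nrow or w > ncol:
                continue
            zvals = _z_offset_values(
                float(window.max()), float(ref.heights.max()), z_step
            )
            support = window > 0
            for row in range(nrow - h + 1):
                for col in range(ncol - w + 1):
                    ref_win = ref.heights[row : row + h, col : col + w]
                    for zi, lift in enumerate(zvals):
                        pair = TrimmedPair(window + lift * support, ref_win)
                        cost = score_cost(score_name, pair, pp)
                        key = (cost, o_idx, row, col, zi, p_idx)
                        if best is None or key < best:
                            best = key
    return best
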