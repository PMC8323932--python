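"""Image similarity scores between pseudo- and reference AFM images.

All four scores are evaluated on a pair of windows trimmed to the minimum
bounding rectangle of the non-zero pixels of the *pseudo* image.  The
trimming keeps a noisy reference background from dominating the score:
only the simulated image decides which pixels count.

Cost conventions (lower is better for the search):

* ``cost = 1 - cosine similarity``     in [0, 1]
* ``cost = 1 - Pearson correlation``   in [0, 2]
* ``cost = pixel-RMSD``                >= 0, in nm
* ``cost = penalty sum``               unbounded
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptySimImageError, UndefinedScoreError
from .imaging import HeightMap

SCORE_NAMES = ("cosine", "correlation", "pixel_rmsd", "penalty")


@dataclass(frozen=True)
class PenaltyParams:
    """Weights of the piecewise penalty score.

    ``thickness`` (nm) is the depth of the favourable band just below the
    reference surface; defaults follow common practice for AFM docking
    penalties: thickness 1.2 nm, k_penalty 10.0, k_reward 1.0.
    """

    thickness: float = 1.2
    k_penalty: float = 10.0
    k_reward: float = 1.0

    def __post_init__(self):
        if not (self.thickness > 0 and self.k_penalty > 0 and self.k_reward > 0):
            raise ValueError("penalty parameters must be positive")


@dataclass(frozen=True)
class TrimmedPair:
    """Same-shape sim/ref windows cut to the sim image's non-zero support."""

    sim: np.ndarray
    ref: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.sim, dtype=float)
        r = np.asarray(self.ref, dtype=float)
        if s.shape != r.shape:
            raise ValueError(f"window shapes differ: {s.shape} vs {r.shape}")
        object.__setattr__(self, "sim", s)
        object.__setattr__(self, "ref", r)

    @property
    def n_pixels(self) -> int:
        return self.sim.size


def nonzero_bbox(heights: np.ndarray) -> tuple[int, int, int, int]:
    """Half-open bounding rectangle (r0, r1, c0, c1) of strictly positive pixels."""
    mask = heights > 0
    if not mask.any():
        raise EmptySimImageError("pseudo-AFM image has no non-zero pixel")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return rows[0], rows[-1] + 1, cols[0], cols[-1] + 1


def trim(sim: HeightMap, ref: HeightMap, offset: tuple[int, int] = (0, 0)) -> TrimmedPair:
    """Trim both images to the sim image's non-zero bounding rectangle.

    ``offset = (row, col)`` places sim pixel (0, 0) on that reference
    pixel; the trimmed sim window must lie fully inside the reference.
    """
    r0, r1, c0, c1 = nonzero_bbox(sim.heights)
    orow, ocol = offset
    rr0, rr1 = orow + r0, orow + r1
    rc0, rc1 = ocol + c0, ocol + c1
    nrow, ncol = ref.heights.shape
    if rr0 < 0 or rc0 < 0 or rr1 > nrow or rc1 > ncol:
        raise IndexError(
            f"sim window rows {rr0}:{rr1} cols {rc0}:{rc1} falls outside "
            f"the {nrow}x{ncol} reference"
        )
    return TrimmedPair(sim.heights[r0:r1, c0:c1], ref.heights[rr0:rr1, rc0:rc1])


def cosine_similarity(pair: TrimmedPair) -> float:
    """Cosine similarity of the two windows viewed as vectors, in [0, 1].

    Unlike the Pearson correlation the means are not removed, so the score
    sees absolute heights; it is invariant to uniform scaling only.
    """
    s, r = pair.sim.ravel(), pair.ref.ravel()
    denom = np.linalg.norm(s) * np.linalg.norm(r)
    if denom == 0:
        raise UndefinedScoreError("zero-norm window in cosine similarity")
    return float(np.dot(s, r) / denom)


def cosine_cost(pair: TrimmedPair) -> float:
    return 1.0 - cosine_similarity(pair)


def correlation_coefficient(pair: TrimmedPair) -> float:
    """Pearson correlation of pixel heights, in [-1, 1].

    Invariant to uniform scaling and uniform shifting of either window.
    """
    s, r = pair.sim.ravel(), pair.ref.ravel()
    s = s - s.mean()
    r = r - r.mean()
    denom = np.linalg.norm(s) * np.linalg.norm(r)
    if denom == 0:
        raise UndefinedScoreError("zero-variance window in correlation")
    return float(np.dot(s, r) / denom)


def correlation_cost(pair: TrimmedPair) -> float:
    return 1.0 - correlation_coefficient(pair)


def pixel_rmsd(pair: TrimmedPair) -> float:
    """Root-mean-square difference of pixel heights (nm); 0 iff identical."""
    diff = pair.sim - pair.ref
    return float(np.sqrt(np.mean(diff * diff)))


def penalty(pair: TrimmedPair, params: PenaltyParams = PenaltyParams()) -> float:
    """Piecewise overlap penalty.

    Per pixel: ``+k_penalty`` where the pseudo image pokes above the
    reference surface (forbidden), ``-k_reward`` where it sits within
    ``thickness`` below the reference (favourable), 0 further below
    (neutral).  The penalty branch wins at the overlap of the two
    conditions, so the reward band is ``ref - thickness < sim <= ref``.
    Not symmetric in (sim, ref).
    """
    s, r = pair.sim, pair.ref
    over = r < s
    reward = ~over & (r < s + params.thickness)
    return float(params.k_penalty * over.sum() - params.k_reward * reward.sum())


_COST_FUNCS = {
    "cosine": cosine_cost,
    "correlation": correlation_cost,
    "pixel_rmsd": pixel_rmsd,
}


def score_cost(name: str, pair: TrimmedPair, penalty_params: PenaltyParams | None = None) -> float:
    """Dispatch a cost by score name; undefined scores map to ``inf``.

    The exhaustive search minimizes this value, so a window on which the
    score is mathematically undefined is simply never selected.
    """
    if name == "penalty":
        return penalty(pair, penalty_params or PenaltyParams())
    if name not in _COST_FUNCS:
        raise ValueError(f"unknown score {name!r}; choose from {SCORE_NAMES}")
    try:
        return _COST_FUNCS[name](pair)
    except UndefinedScoreError:
        return float("inf")
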