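"""Twin-experiment harness: recover a known placement and probe shape.

A twin experiment validates the fitting method against itself: a ground
truth (molecule placement + probe shape) is chosen, a reference image is
rendered from it, independent noise realizations are added, and the
exhaustive search is asked to recover the truth from each noisy image.
The template structure is scrambled by random rotations about X, Y and Z
beforehand so the exact truth orientation is not a grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .fixtures import GroundTruth, make_reference, random_axis_rotation
from .imaging import ProbeShape, add_noise
from .scores import PenaltyParams
from .search import DEFAULT_Z_STEP, default_probe_grid, exhaustive_search_multi
from .structure import (
    AtomicModel,
    RigidTransform,
    ground_on_stage,
    structure_rmsd,
    windowed_filament_rmsd,
)


@dataclass
class TwinReport:
    """Outcome of one twin experiment.

    ``best`` has one row per (replicate, score): the global best probe,
    cost and structure-RMSD.  ``per_probe`` has one row per (replicate,
    score, probe): the best cost and RMSD achieved with that probe fixed,
    the raw material for cost-vs-probe curves.
    """

    truth: GroundTruth
    n_replicates: int
    best: pd.DataFrame
    per_probe: pd.DataFrame
    score_names: tuple = ()
    config: dict = field(default_factory=dict)

    def recovery_count(self, score_name: str, truth_probe: ProbeShape | None = None) -> int:
        """Replicates whose global-argmin probe equals the truth (grid equality)."""
        probe = truth_probe or self.truth.probe
        sub = self.best[self.best.score == score_name]
        hit = (sub.probe_radius == probe.radius) & (
            sub.probe_angle == probe.half_angle_deg
        )
        return int(hit.sum())

    def radius_recovery_count(self, score_name: str) -> int:
        """Replicates recovering the truth probe radius (angle ignored)."""
        sub = self.best[self.best.score == score_name]
        return int((sub.probe_radius == self.truth.probe_radius).sum())

    def rmsd_summary(self) -> pd.DataFrame:
        return self.best.groupby("score").rmsd.agg(["mean", "min", "max"])


def recovery_count(report: TwinReport, truth_probe: ProbeShape, score_name: str | None = None):
    """Number of replicates whose best probe equals ``truth_probe``.

    With several scores in the report and no ``score_name``, a dict keyed
    by score is returned.
    """
    names = report.score_names or tuple(report.best.score.unique())
    if score_name is not None:
        return report.recovery_count(score_name, truth_probe)
    if len(names) == 1:
        return report.recovery_count(names[0], truth_probe)
    return {s: report.recovery_count(s, truth_probe) for s in names}


def _result_rmsd(result, template, truth_model, monomer_atoms):
    placed = result.place(template)
    if monomer_atoms is not None and len(template) < len(truth_model):
        return windowed_filament_rmsd(placed, truth_model, monomer_atoms)
    return structure_rmsd(placed, truth_model)


def run_twin(
    model: AtomicModel,
    truth_probe: ProbeShape,
    pixel_size: float = 1.0,
    n_replicates: int = 10,
    noise_sd: float = 0.3,
    score_names: Sequence[str] | str = ("cosine",),
    probes: Sequence[ProbeShape] | None = None,
    step: float = 10.0,
    z_step: float = DEFAULT_Z_STEP,
    seed: int = 0,
    template: AtomicModel | None = None,
    monomer_atoms: int | None = None,
    perturb: bool = True,
    margin_px: int = 4,
    ring_multiplier: int = 4,
    penalty_params: PenaltyParams | None = None,
) -> TwinReport:
    """Run a complete twin experiment.

    The model is OBB-grounded and rendered with ``truth_probe`` into a
    reference image; each replicate adds an independent Gaussian noise
    realization (seed ``seed + 1 + replicate``) and runs the exhaustive
    search with every requested score.  ``template`` lets a sub-structure
    (e.g. a shorter filament) be fitted against a longer truth; its
    placement is then scored by the windowed structure-RMSD over all
    registrations (``monomer_atoms`` names the repeat unit).

    With ``perturb=True`` (default) the template is scrambled once by
    random rotations about the X, Y and Z axes (seeded) so the exact
    truth orientation is off-grid, as a real experiment's would be.
    """
    if isinstance(score_names, str):
        score_names = (score_names,)
    probes = list(probes) if probes is not None else default_probe_grid()
    ref0, truth_model, record = make_reference(
        model, truth_probe, pixel_size, 0.0, seed, margin_px
    )
    record = GroundTruth(
        record.quaternion, record.translation,
        record.probe_radius, record.probe_angle_deg, seed, noise_sd,
    )
    template = template if template is not None else model
    template = ground_on_stage(template)
    if perturb:
        rot = random_axis_rotation(seed)
        template = template.transformed(RigidTransform(rot, (0.0, 0.0, 0.0)))

    best_rows = []
    probe_rows = []
    for rep in range(n_replicates):
        ref = add_noise(ref0, noise_sd, seed + 1 + rep) if noise_sd > 0 else ref0
        outcomes = exhaustive_search_multi(
            template, ref, probes, tuple(score_names), step, z_step,
            top_k=1, ring_multiplier=ring_multiplier,
            penalty_params=penalty_params,
        )
        for name, outcome in outcomes.items():
            best = outcome.best
            best_rows.append(
                {
                    "replicate": rep,
                    "score": name,
                    "probe_radius": best.probe.radius,
                    "probe_angle": best.probe.half_angle_deg,
                    "cost": best.cost,
                    "rmsd": _result_rmsd(best, template, truth_model, monomer_atoms),
                }
            )
            for res in outcome.per_probe:
                if res is None:
                    continue
                probe_rows.append(
                    {
                        "replicate": rep,
                        "score": name,
                        "probe_radius": res.probe.radius,
                        "probe_angle": res.probe.half_angle_deg,
                        "cost": res.cost,
                        "rmsd": _result_rmsd(res, template, truth_model, monomer_atoms),
                    }
                )
    return TwinReport(
        truth=record,
        n_replicates=n_replicates,
        best=pd.DataFrame(best_rows),
        per_probe=pd.DataFrame(probe_rows),
        score_names=tuple(score_names),
        config={
            "pixel_size": pixel_size,
            "noise_sd": noise_sd,
            "step": step,
            "z_step": z_step,
            "seed": seed,
            "perturb": perturb,
            "probes": [(p.radius, p.half_angle_deg) for p in probes],
        },
    )
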