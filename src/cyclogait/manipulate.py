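"""Variable-manipulation analysis: dominant gait parameters per sub-phase.

Phase 3 of the pipeline.  For each gait sub-phase, the coupled pair with
the highest mean normalized error (from the disparity stage) is taken and
one of its two variables is replaced — at the samples belonging to that
sub-phase only — by the conventional trial-averaged normal values.  The
modified trials are re-simulated through the *unchanged* trained network
and the per-sub-phase errors recomputed.  Repeating this for the other
variable of the pair gives two candidate experiments per sub-phase; the
variable whose substitution yields the lowest own-phase error is the
dominant parameter of that sub-phase.

Two qualitative rules from the protocol are implemented:

* ties — when both candidates land within tolerance of each other, both
  variables are reported (manipulating either yields the same result);
* the no-parameter rule — when neither candidate improves the own-phase
  error, or every candidate worsens a neighboring sub-phase beyond
  tolerance, no parameter is selected (the mid-swing "ballistic" case:
  the limb should swing passively under momentum and gravity).

For prosthetic-knee design the hip/ankle selections are finally mapped to
knee variables (:func:`restrict_to_knee`): the knee variable whose coupled
pair with the selected variable has the lowest disparity-stage error at
that sub-phase takes its place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cyclogram import CyclogramPair, NormalReference
from .disparity import DisparityResults, SubPhaseErrorTable
from .gaitdata import GaitDataError, GaitTrial, SUBPHASE_NAMES

__all__ = [
    "ManipulationExperiment",
    "DominanceResult",
    "substitute_normal",
    "evaluate_candidates",
    "select_dominant",
    "restrict_to_knee",
    "aggregate_dominance",
    "variable_name",
]

VarKey = tuple[str, str]

KNEE_VARIABLES: tuple[VarKey, ...] = (
    ("knee", "angle"),
    ("knee", "moment"),
    ("knee", "power"),
)


def variable_name(varkey: VarKey) -> str:
    """Human-readable variable name, e.g. ``Knee Power``."""
    return f"{varkey[0].capitalize()} {varkey[1].capitalize()}"


def substitute_normal(
    trials: Sequence[GaitTrial],
    pair: CyclogramPair,
    which: VarKey,
    subphase: int,
    reference: NormalReference,
) -> list[GaitTrial]:
    """Insert normal values into one pair variable at one sub-phase.

    In every trial, samples of the chosen variable whose label equals
    ``subphase`` are replaced by the reference mean curve values at the
    same grid points; everything else is untouched.  Idempotent.
    """
    if not pair.contains(which):
        raise GaitDataError(
            f"{which} is not a variable of pair {pair.label}"
        )
    if not 1 <= subphase <= 7:
        raise GaitDataError(f"subphase must be 1..7, got {subphase}")
    normal_curve = reference.curve(which)
    modified = []
    for trial in trials:
        new = trial.copy()
        mask = new.subphase == subphase
        new.series[which][mask] = normal_curve[mask]
        modified.append(new)
    return modified


@dataclass
class ManipulationExperiment:
    """One substitution experiment: one variable, one sub-phase.

    ``pre_errors`` / ``post_errors`` are the full 7-phase mean normalized
    error vectors (×100) before and after substitution, both computed
    through the same trained network.
    """

    subject_id: str
    subphase: int
    pair: CyclogramPair
    manipulated_variable: VarKey
    pre_errors: np.ndarray
    post_errors: np.ndarray

    @property
    def own_pre(self) -> float:
        return float(self.pre_errors[self.subphase - 1])

    @property
    def own_post(self) -> float:
        return float(self.post_errors[self.subphase - 1])


def evaluate_candidates(
    subject_trials: Sequence[GaitTrial],
    worst_table: SubPhaseErrorTable,
    networks: Mapping[CyclogramPair, DisparityResults],
    reference: NormalReference,
    allow_resample: bool = False,
    seed: int | None = None,
) -> list[ManipulationExperiment]:
    """Run both substitution experiments for every evaluable sub-phase.

    For each sub-phase the worst pair (argmax of the disparity table) is
    manipulated once per variable; sub-phases whose network is missing or
    unaccepted are skipped (they never enter the argmax in the first
    place).
    """
    experiments: list[ManipulationExperiment] = []
    for phase in range(1, 8):
        if phase not in worst_table.argmax:
            continue
        pair = worst_table.argmax_pair(phase)
        if pair not in networks or not networks[pair].report.accepted:
            continue
        res = networks[pair]
        pre = worst_table.errors[worst_table.pairs.index(pair)].copy()
        for which in (pair.var_a, pair.var_b):
            modified = substitute_normal(
                subject_trials, pair, which, phase, reference
            )
            post = (
                res.subphase_errors(
                    modified, reference, allow_resample=allow_resample, seed=seed
                )
                * 100.0
            )
            experiments.append(
                ManipulationExperiment(
                    subject_id=worst_table.subject_id,
                    subphase=phase,
                    pair=pair,
                    manipulated_variable=which,
                    pre_errors=pre,
                    post_errors=post,
                )
            )
    return experiments


@dataclass
class DominanceResult:
    """Selected dominant parameter(s) per gait sub-phase for one subject.

    ``selected`` maps each evaluated sub-phase to the chosen variables
    (empty list = no parameter, the mid-swing-style outcome).  ``rationale``
    keeps the per-candidate own-phase and neighbor-phase error deltas that
    justified the choice.  ``unresolved`` lists sub-phases the knee-only
    mapping could not resolve.
    """

    subject_id: str
    selected: dict[int, list[VarKey]]
    rationale: dict[int, list[dict]] = field(default_factory=dict)
    knee_restricted: bool = False
    unresolved: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for phase in sorted(self.selected):
            names = ", ".join(variable_name(v) for v in self.selected[phase]) or "-"
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "subphase": phase,
                    "subphase_name": SUBPHASE_NAMES[phase - 1],
                    "selected": names,
                }
            )
        return pd.DataFrame(rows)


def _neighbors(phase: int) -> tuple[int, int]:
    """The two cyclically adjacent sub-phases (LR and TSw are adjacent)."""
    return (7 if phase == 1 else phase - 1, 1 if phase == 7 else phase + 1)


def select_dominant(
    experiments: Sequence[ManipulationExperiment],
    tolerance: float = 0.05,
) -> DominanceResult:
    """Pick the dominant variable per sub-phase from substitution experiments.

    A candidate is viable when its substitution reduces the own-phase error
    and worsens no neighboring phase by more than ``tolerance`` (relative).
    Among viable candidates the lowest own-phase post-error wins; both are
    reported when within ``tolerance`` of each other.  No viable candidate
    means no parameter is selected for that sub-phase.
    """
    if not experiments:
        raise GaitDataError("select_dominant needs at least one experiment")
    subject_id = experiments[0].subject_id
    by_phase: dict[int, list[ManipulationExperiment]] = {}
    for exp in experiments:
        by_phase.setdefault(exp.subphase, []).append(exp)
    selected: dict[int, list[VarKey]] = {}
    rationale: dict[int, list[dict]] = {}
    for phase, exps in sorted(by_phase.items()):
        records = []
        viable = []
        for exp in exps:
            improves = exp.own_post < exp.own_pre
            neighbor_ok = True
            neighbor_deltas = {}
            for nb in _neighbors(phase):
                pre_nb = exp.pre_errors[nb - 1]
                post_nb = exp.post_errors[nb - 1]
                if np.isnan(pre_nb) or np.isnan(post_nb):
                    continue
                neighbor_deltas[nb] = float(post_nb - pre_nb)
                if post_nb > pre_nb * (1.0 + tolerance):
                    neighbor_ok = False
            records.append(
                {
                    "variable": exp.manipulated_variable,
                    "own_pre": exp.own_pre,
                    "own_post": exp.own_post,
                    "improves_own_phase": improves,
                    "neighbors_ok": neighbor_ok,
                    "neighbor_deltas": neighbor_deltas,
                }
            )
            if improves and neighbor_ok:
                viable.append(exp)
        rationale[phase] = records
        if not viable:
            selected[phase] = []
            continue
        viable.sort(key=lambda e: e.own_post)
        best = viable[0]
        chosen = [best.manipulated_variable]
        for other in viable[1:]:
            if abs(other.own_post - best.own_post) <= tolerance * max(
                best.own_post, other.own_post, 1e-30
            ):
                chosen.append(other.manipulated_variable)
        selected[phase] = chosen
    return DominanceResult(
        subject_id=subject_id, selected=selected, rationale=rationale
    )


def restrict_to_knee(
    dominance: DominanceResult,
    phase2_table: SubPhaseErrorTable,
    tolerance: float = 0.05,
) -> DominanceResult:
    """Map hip/ankle selections to knee variables for knee-only control.

    For any sub-phase whose selected variable is not a knee variable, the
    disparity-stage errors of all pairs coupling that variable with a knee
    variable are compared at that sub-phase; the knee variable of the
    lowest-error pair replaces it (ties within tolerance keep both).  Knee
    selections and "none" outcomes pass through unchanged.
    """
    new_selected: dict[int, list[VarKey]] = {}
    unresolved: list[int] = []
    for phase, variables in dominance.selected.items():
        if not variables:
            new_selected[phase] = []
            continue
        knee_vars: list[VarKey] = []
        for var in variables:
            if var in KNEE_VARIABLES:
                if var not in knee_vars:
                    knee_vars.append(var)
                continue
            candidates: list[tuple[float, VarKey]] = []
            for i, pair in enumerate(phase2_table.pairs):
                if not pair.contains(var):
                    continue
                other = pair.other(var)
                if other not in KNEE_VARIABLES:
                    continue
                err = phase2_table.errors[i, phase - 1]
                if np.isnan(err):
                    continue
                candidates.append((float(err), other))
            if not candidates:
                unresolved.append(phase)
                continue
            candidates.sort(key=lambda c: c[0])
            best_err = candidates[0][0]
            for err, knee_var in candidates:
                within = abs(err - best_err) <= tolerance * max(err, best_err, 1e-30)
                if within and knee_var not in knee_vars:
                    knee_vars.append(knee_var)
        new_selected[phase] = knee_vars
    return DominanceResult(
        subject_id=dominance.subject_id,
        selected=new_selected,
        rationale=dominance.rationale,
        knee_restricted=True,
        unresolved=unresolved,
    )


def aggregate_dominance(results: Sequence[DominanceResult]) -> pd.DataFrame:
    """Majority vote across subjects into a cohort-level dominance table.

    Per sub-phase, each subject votes for its selected variable(s); the
    most frequent selection(s) are reported, ties included.  A "none"
    outcome counts as a vote too.
    """
    rows = []
    for phase in range(1, 8):
        votes: dict[str, int] = {}
        evaluated = 0
        for res in results:
            if phase not in res.selected:
                continue
            evaluated += 1
            names = [variable_name(v) for v in res.selected[phase]] or ["-"]
            for name in names:
                votes[name] = votes.get(name, 0) + 1
        if not evaluated:
            continue
        top = max(votes.values())
        winners = sorted(k for k, v in votes.items() if v == top)
        rows.append(
            {
                "subphase": phase,
                "subphase_name": SUBPHASE_NAMES[phase - 1],
                "selected": ", ".join(winners),
                "n_subjects": evaluated,
                "votes": votes,
            }
        )
    return pd.DataFrame(rows)
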