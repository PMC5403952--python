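"""Cyclogram pairs, trajectories and the trial-averaged normal reference.

A cyclogram plots two gait variables against each other over one stride,
omitting time.  Pairing the 9 sagittal variables (3 joints × angle, moment,
power) within and across joints yields exactly 36 coupled relationships in
6 groups:

* angle–angle, moment–moment, power–power: across-joint pairs only
  (3 each — a variable is never plotted against itself);
* angle–moment, angle–power, moment–power: within-joint plus across-joint
  pairs (9 each — all 3×3 ordered joint combinations, with the first-named
  variable type as the x-variable).

The normal reference is the conventional trial-averaged curve set: a
pointwise mean of many normal trials on the percent-of-cycle grid.
Pathological trials are never averaged — their sub-phase durations are too
irregular — so each pathological trial keeps its own curves and labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
import json

import numpy as np
import pandas as pd

from .gaitdata import (
    GaitDataError,
    GaitTrial,
    JOINTS,
    N_SAMPLES,
    STRIDE_GRID,
    VARKEYS,
)

__all__ = [
    "GROUPS",
    "CyclogramPair",
    "Cyclogram",
    "NormalReference",
    "enumerate_pairs",
    "build_cyclogram",
    "average_reference",
]

VarKey = tuple[str, str]

#: canonical group order
GROUPS: tuple[str, ...] = (
    "angle-angle",
    "moment-moment",
    "power-power",
    "angle-moment",
    "angle-power",
    "moment-power",
)

_ABBREV = {"angle": "θ", "moment": "M", "power": "P"}


@dataclass(frozen=True)
class CyclogramPair:
    """Identity of one coupled-variable relationship."""

    var_a: VarKey
    var_b: VarKey
    group: str

    def __post_init__(self) -> None:
        if self.var_a == self.var_b:
            raise GaitDataError("a cyclogram pair must couple distinct variables")

    @property
    def label(self) -> str:
        """Compact label, e.g. ``K0-AP`` style ``Kθ-AP`` for knee angle vs ankle power."""
        (ja, va), (jb, vb) = self.var_a, self.var_b
        return f"{ja[0].upper()}{_ABBREV[va]}-{jb[0].upper()}{_ABBREV[vb]}"

    def contains(self, varkey: VarKey) -> bool:
        return varkey == self.var_a or varkey == self.var_b

    def other(self, varkey: VarKey) -> VarKey:
        if varkey == self.var_a:
            return self.var_b
        if varkey == self.var_b:
            return self.var_a
        raise GaitDataError(f"{varkey} is not a member of pair {self.label}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_pairs() -> list[CyclogramPair]:
    """Enumerate the 36 canonical cyclogram pairs in stable order.

    Same-type groups pair distinct joints (ankle<knee<hip order); mixed
    groups take every ordered (joint_a, joint_b) combination with the
    first-named variable type on joint_a, giving 3 within-joint and 6
    across-joint pairs per group.
    """
    pairs: list[CyclogramPair] = []
    for group in GROUPS:
        type_a, type_b = group.split("-")
        if type_a == type_b:
            for i, ja in enumerate(JOINTS):
                for jb in JOINTS[i + 1 :]:
                    pairs.append(CyclogramPair((ja, type_a), (jb, type_b), group))
        else:
            for ja in JOINTS:
                for jb in JOINTS:
                    pairs.append(CyclogramPair((ja, type_a), (jb, type_b), group))
    return pairs


@dataclass
class Cyclogram:
    """A realized closed trajectory of one pair from one trial (or reference).

    Sample 50 is interpreted as connecting back to sample 1: the trajectory
    is a closed loop over the gait cycle.
    """

    pair: CyclogramPair
    a_values: np.ndarray
    b_values: np.ndarray
    subphase: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.a_values = np.asarray(self.a_values, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if not (len(self.a_values) == len(self.b_values) == len(self.subphase)):
            raise GaitDataError("cyclogram component lengths must agree")


def build_cyclogram(trial: GaitTrial, pair: CyclogramPair) -> Cyclogram:
    """Project a trial onto one coupled-variable trajectory."""
    return Cyclogram(
        pair=pair,
        a_values=trial.series[pair.var_a].copy(),
        b_values=trial.series[pair.var_b].copy(),
        subphase=trial.subphase.copy(),
        source=f"{trial.subject_id}/trial{trial.trial_index}",
    )


@dataclass
class NormalReference:
    """Conventional trial-averaged normal curves for all 9 variables.

    ``means`` maps each (joint, variable) to its 50-point mean curve;
    ``ranges`` holds max−min of each mean curve, the normalization
    denominator used by every downstream error statistic.  ``subphase``
    carries the canonical sub-phase labels of the averaged cohort.
    """

    means: dict[VarKey, np.ndarray]
    ranges: dict[VarKey, float]
    subphase: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        for key, rng in self.ranges.items():
            if not rng > 0:
                raise GaitDataError(
                    f"reference range for {key} must be positive, got {rng}"
                )

    def curve(self, varkey: VarKey) -> np.ndarray:
        return self.means[varkey]

    def to_files(self, csv_path: str | Path, meta_path: str | Path) -> None:
        rows = []
        for (joint, variable), curve in self.means.items():
            for p, value in zip(STRIDE_GRID.astype(int), curve):
                rows.append(
                    {
                        "variable": f"{joint}_{variable}",
                        "percent_gait": p,
                        "mean_value": value,
                    }
                )
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        meta = {
            "n_trials": self.n_trials,
            "ranges": {
                f"{j}_{v}": r for (j, v), r in self.ranges.items()
            },
            "subphase": self.subphase.astype(int).tolist(),
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_files(
        cls, csv_path: str | Path, meta_path: str | Path
    ) -> "NormalReference":
        frame = pd.read_csv(csv_path)
        meta = json.loads(Path(meta_path).read_text())
        means: dict[VarKey, np.ndarray] = {}
        for name, block in frame.groupby("variable", sort=False):
            joint, variable = name.split("_", 1)
            block = block.sort_values("percent_gait")
            means[(joint, variable)] = block["mean_value"].to_numpy(dtype=float)
        ranges = {
            tuple(k.split("_", 1)): float(v) for k, v in meta["ranges"].items()
        }
        return cls(
            means=means,
            ranges=ranges,
            subphase=np.asarray(meta["subphase"], dtype=int),
            n_trials=int(meta["n_trials"]),
        )


def _canonical_labels(trials: Sequence[GaitTrial]) -> np.ndarray:
    """Pointwise modal sub-phase label, repaired to satisfy trial invariants."""
    stack = np.stack([t.subphase for t in trials])
    labels = np.empty(N_SAMPLES, dtype=int)
    for i in range(N_SAMPLES):
        values, counts = np.unique(stack[:, i], return_counts=True)
        labels[i] = values[np.argmax(counts)]  # ties -> smallest label
    labels = np.maximum.accumulate(labels)  # enforce non-decreasing
    # guarantee every phase appears at least once (jitter could swallow one)
    for phase in range(1, 8):
        if phase not in labels:
            anchor = np.searchsorted(labels, phase)
            anchor = min(anchor, N_SAMPLES - (8 - phase))
            labels[anchor] = phase
            labels = np.maximum.accumulate(labels)
    return labels


def average_reference(trials: Sequence[GaitTrial]) -> NormalReference:
    """Pointwise mean of normal trials on the stride grid.

    Only normal-cohort trials may be averaged; pathological sub-phase
    durations are too irregular for pointwise averaging to be meaningful.
    """
    trials = list(trials)
    if not trials:
        raise GaitDataError("cannot average an empty trial list")
    cohorts = {t.cohort for t in trials}
    if cohorts != {"normal"}:
        raise GaitDataError(
            f"reference averaging accepts only the normal cohort, got {sorted(cohorts)}"
        )
    means: dict[VarKey, np.ndarray] = {}
    ranges: dict[VarKey, float] = {}
    for key in VARKEYS:
        stack = np.stack([t.series[key] for t in trials])
        mean = stack.mean(axis=0)
        means[key] = mean
        ranges[key] = float(mean.max() - mean.min())
    return NormalReference(
        means=means,
        ranges=ranges,
        subphase=_canonical_labels(trials),
        n_trials=len(trials),
    )
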