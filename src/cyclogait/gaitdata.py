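"""Data model and I/O for stride-normalized lower-limb gait trials.

A trial is one stride of one subject, sampled on a fixed 50-point grid at
every 2% of the gait cycle (0, 2, ..., 98%).  Nine sagittal-plane series are
carried per trial — angle (deg), moment (N·m/kg) and power (W/kg) for the
ankle, knee and hip — together with a per-sample gait sub-phase label 1..7
(loading response, mid-stance, terminal stance, pre-swing, initial swing,
mid-swing, terminal swing).

Besides the :class:`GaitTrial` container this module provides the standard
pre-processing steps applied to raw lab signals before they reach the
stride grid: linear resampling onto the 2% lattice, body-mass normalization
of joint moments, and zero-phase second-order Butterworth smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "JOINTS",
    "VARIABLES",
    "VARKEYS",
    "COHORTS",
    "SUBPHASE_NAMES",
    "N_SAMPLES",
    "STRIDE_GRID",
    "GaitDataError",
    "SchemaError",
    "CoverageError",
    "GaitTrial",
    "RawSeries",
    "resample_to_stride_grid",
    "normalize_moment",
    "smooth_series",
    "read_trials",
    "write_trials",
    "trials_to_frame",
]

JOINTS: tuple[str, ...] = ("ankle", "knee", "hip")
VARIABLES: tuple[str, ...] = ("angle", "moment", "power")
#: canonical ordering of the 9 (joint, variable) series of a trial
VARKEYS: tuple[tuple[str, str], ...] = tuple(
    (j, v) for v in VARIABLES for j in JOINTS
)
COHORTS: tuple[str, ...] = ("normal", "transtibial", "transfemoral", "orthosis")
SUBPHASE_NAMES: tuple[str, ...] = ("LR", "MSt", "TSt", "PSw", "ISw", "MSw", "TSw")
N_SAMPLES: int = 50
#: percent-of-gait-cycle lattice: 0, 2, ..., 98
STRIDE_GRID: np.ndarray = np.arange(0, 100, 2, dtype=float)

_UNITS = {"angle": "deg", "moment": "nm_kg", "power": "w_kg"}


class GaitDataError(ValueError):
    """Base class for gait-data validation failures."""


class SchemaError(GaitDataError):
    """A trial file or record violates the trial schema."""


class CoverageError(GaitDataError):
    """A raw series does not cover the stride interval to be resampled."""


def _series_column(joint: str, variable: str) -> str:
    return f"{joint}_{variable}_{_UNITS[variable]}"


@dataclass
class GaitTrial:
    """One stride of one subject on the 50-point stride grid.

    Parameters
    ----------
    subject_id : str
        Subject identifier (e.g. ``"N01"``, ``"TF3"``).
    cohort : str
        One of ``normal``, ``transtibial``, ``transfemoral``, ``orthosis``.
    trial_index : int
        Trial number within the subject's session.
    side : str
        ``left`` or ``right``.  Analyses default to the left (non-dominant)
        side, matching the support role of the prosthetic limb.
    series : mapping
        ``(joint, variable) -> 50 values``; exactly the 9 keys in
        :data:`VARKEYS`.
    subphase : array of int
        50 labels in 1..7, non-decreasing, covering every sub-phase.
    """

    subject_id: str
    cohort: str
    trial_index: int
    side: str
    series: dict[tuple[str, str], np.ndarray]
    subphase: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise SchemaError(
                f"cohort {self.cohort!r} not in allowed values {COHORTS}"
            )
        if self.side not in ("left", "right"):
            raise SchemaError(f"side {self.side!r} must be 'left' or 'right'")
        if set(self.series) != set(VARKEYS):
            missing = set(VARKEYS) - set(self.series)
            extra = set(self.series) - set(VARKEYS)
            raise SchemaError(
                f"trial must carry exactly the 9 canonical series; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        self.series = {
            k: np.asarray(v, dtype=float) for k, v in self.series.items()
        }
        for key, values in self.series.items():
            if values.shape != (N_SAMPLES,):
                raise SchemaError(
                    f"series {key} has length {values.shape}, expected {N_SAMPLES}"
                )
        self.subphase = np.asarray(self.subphase)
        if self.subphase.shape != (N_SAMPLES,):
            raise SchemaError(
                f"subphase has length {self.subphase.shape}, expected {N_SAMPLES}"
            )
        if not np.issubdtype(self.subphase.dtype, np.integer):
            as_int = self.subphase.astype(int)
            if not np.array_equal(as_int, self.subphase):
                raise SchemaError("subphase labels must be integers")
            self.subphase = as_int
        labels = self.subphase
        if labels.min() < 1 or labels.max() > 7:
            raise SchemaError("subphase labels must lie in 1..7")
        if np.any(np.diff(labels) < 0):
            raise SchemaError("subphase labels must be non-decreasing")
        if set(np.unique(labels)) != set(range(1, 8)):
            raise SchemaError("subphase labels must take every value 1..7")

    def copy(self) -> "GaitTrial":
        return GaitTrial(
            subject_id=self.subject_id,
            cohort=self.cohort,
            trial_index=self.trial_index,
            side=self.side,
            series={k: v.copy() for k, v in self.series.items()},
            subphase=self.subphase.copy(),
        )

    def phase_samples(self, subphase: int) -> np.ndarray:
        """Indices of grid samples labeled with the given sub-phase."""
        return np.flatnonzero(self.subphase == subphase)


@dataclass
class RawSeries:
    """A raw lab signal with the two foot-strike events delimiting a stride."""

    timestamps: np.ndarray
    values: np.ndarray
    gait_events: tuple[float, float]  # ipsilateral foot strike -> foot strike

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise SchemaError("raw series needs at least 2 samples")
        if self.values.shape != self.timestamps.shape:
            raise SchemaError("timestamps and values must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise SchemaError("timestamps must be strictly increasing")
        t0, t1 = self.gait_events
        if not t1 > t0:
            raise SchemaError("stride end event must follow the start event")


def resample_to_stride_grid(raw: RawSeries) -> np.ndarray:
    """Linearly interpolate a raw signal onto the 50-point stride grid.

    Grid times are ``t0 + p/100 * (t1 - t0)`` for ``p = 0, 2, ..., 98`` where
    ``(t0, t1)`` are the stride-delimiting foot strikes.
    """
    t0, t1 = raw.gait_events
    grid_times = t0 + STRIDE_GRID / 100.0 * (t1 - t0)
    if grid_times[0] < raw.timestamps[0] or grid_times[-1] > raw.timestamps[-1]:
        raise CoverageError(
            "raw samples do not cover the stride interval "
            f"[{grid_times[0]:g}, {grid_times[-1]:g}] s"
        )
    return np.interp(grid_times, raw.timestamps, raw.values)


def normalize_moment(moment_series: np.ndarray, body_mass: float) -> np.ndarray:
    """Divide a joint moment series (N·m) by body mass (kg) -> N·m/kg."""
    if not body_mass > 0:
        raise GaitDataError(f"body mass must be positive, got {body_mass}")
    return np.asarray(moment_series, dtype=float) / float(body_mass)


def smooth_series(
    values: np.ndarray, cutoff: float, sample_rate: float
) -> np.ndarray:
    """Zero-phase second-order Butterworth low-pass smoothing.

    Applied forward-backward (``filtfilt``) so the output has no phase lag,
    which would otherwise shift sub-phase alignment.  DC gain is unity, so a
    constant series passes through unchanged.
    """
    nyquist = sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise GaitDataError(
            f"cutoff must lie in (0, Nyquist={nyquist:g}), got {cutoff}"
        )
    b, a = butter(2, cutoff / nyquist)
    return filtfilt(b, a, np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# CSV I/O: one row per (trial, grid point)

_META_COLUMNS = ["subject_id", "cohort", "trial_index", "side"]
_SERIES_COLUMNS = [_series_column(j, v) for (j, v) in VARKEYS]
_ALL_COLUMNS = _META_COLUMNS + ["percent_gait", "subphase"] + _SERIES_COLUMNS


def trials_to_frame(trials: Iterable[GaitTrial]) -> pd.DataFrame:
    """Flatten trials into the long tabular schema (one row per grid point)."""
    records = []
    for trial in trials:
        block = {
            "subject_id": trial.subject_id,
            "cohort": trial.cohort,
            "trial_index": trial.trial_index,
            "side": trial.side,
            "percent_gait": STRIDE_GRID.astype(int),
            "subphase": trial.subphase,
        }
        for key in VARKEYS:
            block[_series_column(*key)] = trial.series[key]
        records.append(pd.DataFrame(block))
    if not records:
        return pd.DataFrame(columns=_ALL_COLUMNS)
    return pd.concat(records, ignore_index=True)[_ALL_COLUMNS]


def write_trials(trials: Sequence[GaitTrial], path: str | Path) -> None:
    """Write trials to CSV (UTF-8, '.' decimal, header) at full precision."""
    frame = trials_to_frame(trials)
    frame.to_csv(path, index=False)


def _trial_from_block(block: pd.DataFrame) -> GaitTrial:
    if len(block) != N_SAMPLES:
        ident = block.iloc[0][_META_COLUMNS].tolist()
        raise SchemaError(
            f"trial {ident} has {len(block)} rows, expected {N_SAMPLES}"
        )
    block = block.sort_values("percent_gait")
    if not np.array_equal(block["percent_gait"].to_numpy(dtype=float), STRIDE_GRID):
        raise SchemaError("percent_gait must be exactly 0, 2, ..., 98")
    first = block.iloc[0]
    series = {
        key: block[_series_column(*key)].to_numpy(dtype=float) for key in VARKEYS
    }
    return GaitTrial(
        subject_id=str(first["subject_id"]),
        cohort=str(first["cohort"]),
        trial_index=int(first["trial_index"]),
        side=str(first["side"]),
        series=series,
        subphase=block["subphase"].to_numpy(),
    )


def read_trials(path: str | Path) -> list[GaitTrial]:
    """Read trials from the CSV schema, validating every invariant."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _ALL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial file {path} is missing columns {missing}")
    trials = []
    for _, block in frame.groupby(
        ["subject_id", "cohort", "trial_index", "side"], sort=False
    ):
        trials.append(_trial_from_block(block))
    return trials
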