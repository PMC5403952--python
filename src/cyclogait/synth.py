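"""Synthetic gait-trial generator for normal and pathological cohorts.

No public dataset ships the stride-normalized joint curves this pipeline
consumes, so the generator emulates them: smooth periodic templates
approximating normative sagittal gait curves (periodic cubic splines
through hand-set keypoints in the style of standard gait-lab normative
plots), perturbed per cohort.

The statistical structure mirrors what the analysis assumes:

* normal subjects walk with stable sub-phase durations (boundaries within
  ±2% of the canonical Rancho-convention boundaries) and small
  trial-to-trial noise, so conventional pointwise trial averaging is
  meaningful;
* pathological cohorts (transtibial, transfemoral, orthosis) have
  attenuated or offset joint kinetics — applied per sub-phase through a
  :class:`CohortProfile` — plus irregular sub-phase durations, so their
  trials are analyzed individually, never averaged.

Noise model: per-sample additive Gaussian noise (scaled to a fraction of
each variable's template range) smoothed with a short circular kernel,
plus a constant per-subject offset shared across that subject's trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .gaitdata import (
    GaitTrial,
    JOINTS,
    N_SAMPLES,
    STRIDE_GRID,
    VARKEYS,
    VARIABLES,
)

__all__ = [
    "CANONICAL_PHASE_STARTS",
    "canonical_subphase_labels",
    "TemplateBank",
    "CohortProfile",
    "default_templates",
    "default_profiles",
    "generate_trial",
    "generate_cohort",
]

VarKey = tuple[str, str]

#: first grid sample of each sub-phase under the canonical convention
#: LR 0–10%, MSt 10–30%, TSt 30–50%, PSw 50–60%, ISw 60–73%, MSw 73–87%,
#: TSw 87–100% of the gait cycle.
CANONICAL_PHASE_STARTS: tuple[int, ...] = (0, 5, 15, 25, 30, 37, 44)


def canonical_subphase_labels() -> np.ndarray:
    """The 50 canonical sub-phase labels (1..7) on the stride grid."""
    return _labels_from_starts(CANONICAL_PHASE_STARTS)


def _labels_from_starts(starts: Sequence[int]) -> np.ndarray:
    labels = np.empty(N_SAMPLES, dtype=int)
    bounds = list(starts) + [N_SAMPLES]
    for phase in range(7):
        labels[bounds[phase] : bounds[phase + 1]] = phase + 1
    return labels


# ---------------------------------------------------------------------------
# Normative templates

# Keypoints (percent of cycle, value) for each sagittal variable; signs:
# flexion/dorsiflexion positive, extensor moment positive, power positive
# = generation.  Values are plausible normative magnitudes (angle deg,
# moment N·m/kg, power W/kg), not digitized from any source.
_KEYPOINTS: dict[VarKey, list[tuple[float, float]]] = {
    ("ankle", "angle"): [
        (0, 0.0), (6, -5.0), (12, -2.0), (30, 5.0), (45, 10.0), (52, 5.0),
        (62, -18.0), (70, -8.0), (80, 0.0), (92, 1.0),
    ],
    ("knee", "angle"): [
        (0, 5.0), (12, 18.0), (30, 10.0), (44, 4.0), (56, 30.0), (66, 55.0),
        (74, 60.0), (86, 35.0), (94, 10.0),
    ],
    ("hip", "angle"): [
        (0, 30.0), (20, 15.0), (38, 0.0), (52, -10.0), (62, 2.0), (76, 22.0),
        (88, 32.0), (96, 31.0),
    ],
    ("ankle", "moment"): [
        (0, 0.0), (8, -0.2), (18, 0.3), (34, 0.7), (46, 1.4), (52, 1.1),
        (58, 0.2), (66, 0.0), (90, 0.0),
    ],
    ("knee", "moment"): [
        (0, -0.05), (8, 0.35), (16, 0.5), (30, 0.0), (44, -0.2), (52, 0.1),
        (62, -0.1), (76, 0.0), (92, 0.05),
    ],
    ("hip", "moment"): [
        (0, 0.4), (10, 0.8), (28, 0.2), (44, -0.7), (54, -0.9), (64, -0.2),
        (78, 0.1), (92, 0.25),
    ],
    ("ankle", "power"): [
        (0, 0.0), (10, -0.4), (30, -0.4), (44, -0.8), (52, 2.8), (58, 1.2),
        (66, 0.0), (90, 0.0),
    ],
    ("knee", "power"): [
        (0, -0.3), (8, -0.8), (18, 0.5), (36, -0.1), (50, -0.9), (60, -1.3),
        (70, -0.4), (82, 0.0), (92, -1.1),
    ],
    ("hip", "power"): [
        (0, 0.3), (14, 1.0), (32, -0.2), (46, -0.6), (56, 0.9), (66, 0.5),
        (80, 0.0), (92, 0.2),
    ],
}


@dataclass
class TemplateBank:
    """Smooth periodic templates on the stride grid plus canonical labels."""

    curves: dict[VarKey, np.ndarray]
    subphase: np.ndarray = field(
        default_factory=canonical_subphase_labels
    )

    def __post_init__(self) -> None:
        self.curves = {k: np.asarray(v, dtype=float) for k, v in self.curves.items()}
        for key, curve in self.curves.items():
            if curve.shape != (N_SAMPLES,):
                raise ValueError(f"template {key} must have {N_SAMPLES} samples")

    def range(self, varkey: VarKey) -> float:
        curve = self.curves[varkey]
        return float(curve.max() - curve.min())


def default_templates() -> TemplateBank:
    """Build the default normative template bank from periodic splines."""
    curves: dict[VarKey, np.ndarray] = {}
    for key, points in _KEYPOINTS.items():
        pct = np.array([p for p, _ in points], dtype=float)
        val = np.array([v for _, v in points], dtype=float)
        # close the cycle: periodic spline requires first value == last value
        pct = np.append(pct, 100.0)
        val = np.append(val, val[0])
        spline = CubicSpline(pct, val, bc_type="periodic")
        curves[key] = spline(STRIDE_GRID)
    return TemplateBank(curves=curves)


# ---------------------------------------------------------------------------
# Cohort profiles

def _ones_per_phase() -> np.ndarray:
    return np.ones(7)


def _zeros_per_phase() -> np.ndarray:
    return np.zeros(7)


@dataclass
class CohortProfile:
    """Per-cohort perturbation recipe.

    ``amplitude_scale`` / ``offset`` map a (joint, variable) to a length-7
    vector (one entry per sub-phase); variables absent from the maps are
    unperturbed.  ``subphase_jitter_sd`` is in percent of the gait cycle;
    noise and offset standard deviations are fractions of each variable's
    template range.
    """

    cohort: str
    amplitude_scale: dict[VarKey, np.ndarray] = field(default_factory=dict)
    offset: dict[VarKey, np.ndarray] = field(default_factory=dict)
    subphase_jitter_sd: float = 0.0
    trial_noise_sd: float = 0.0
    subject_offset_sd: float = 0.0

    def __post_init__(self) -> None:
        self.amplitude_scale = {
            k: np.broadcast_to(np.asarray(v, dtype=float), (7,)).copy()
            for k, v in self.amplitude_scale.items()
        }
        self.offset = {
            k: np.broadcast_to(np.asarray(v, dtype=float), (7,)).copy()
            for k, v in self.offset.items()
        }
        for key, scale in self.amplitude_scale.items():
            if np.any(scale < 0):
                raise ValueError(f"amplitude scales must be >= 0 ({key})")
        if self.subphase_jitter_sd < 0:
            raise ValueError("subphase_jitter_sd must be >= 0")

    def scale_for(self, varkey: VarKey) -> np.ndarray:
        return self.amplitude_scale.get(varkey, _ones_per_phase())

    def offset_for(self, varkey: VarKey) -> np.ndarray:
        return self.offset.get(varkey, _zeros_per_phase())

    def is_degenerate(self) -> bool:
        """True when every variable is scaled to zero in every phase."""
        if len(self.amplitude_scale) < len(VARKEYS):
            return False
        return all(
            np.all(self.scale_for(key) == 0.0) for key in VARKEYS
        )

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "amplitude_scale": {
                f"{j}_{v}": s.tolist() for (j, v), s in self.amplitude_scale.items()
            },
            "offset": {
                f"{j}_{v}": o.tolist() for (j, v), o in self.offset.items()
            },
            "subphase_jitter_sd": self.subphase_jitter_sd,
            "trial_noise_sd": self.trial_noise_sd,
            "subject_offset_sd": self.subject_offset_sd,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortProfile":
        def unkey(d):
            return {tuple(k.split("_", 1)): np.asarray(v) for k, v in d.items()}

        return cls(
            cohort=data["cohort"],
            amplitude_scale=unkey(data.get("amplitude_scale", {})),
            offset=unkey(data.get("offset", {})),
            subphase_jitter_sd=float(data.get("subphase_jitter_sd", 0.0)),
            trial_noise_sd=float(data.get("trial_noise_sd", 0.0)),
            subject_offset_sd=float(data.get("subject_offset_sd", 0.0)),
        )


def default_profiles() -> dict[str, CohortProfile]:
    """Default cohort profiles, ordered by clinical severity.

    Transfemoral users lose the anatomical knee entirely: knee kinetics are
    strongly attenuated and stance knee flexion is stiffened (a typical
    locked- or damped-knee pattern), with a compliant prosthetic-foot ankle.
    Transtibial users keep the knee but lose the ankle plantar-flexors;
    orthosis users show a mild global kinetic attenuation.
    """
    stance_only = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0])

    def flat(x: float) -> np.ndarray:
        return np.full(7, x)

    def stance(x: float) -> np.ndarray:
        # scale applied during stance phases (LR..PSw), unity in swing
        return np.where(stance_only > 0, x, 1.0)

    return {
        "normal": CohortProfile(
            cohort="normal",
            subphase_jitter_sd=0.5,
            trial_noise_sd=0.02,
            subject_offset_sd=0.02,
        ),
        "orthosis": CohortProfile(
            cohort="orthosis",
            amplitude_scale={
                (j, v): flat(0.85) for j in JOINTS for v in ("moment", "power")
            },
            subphase_jitter_sd=1.5,
            trial_noise_sd=0.03,
            subject_offset_sd=0.03,
        ),
        "transtibial": CohortProfile(
            cohort="transtibial",
            amplitude_scale={
                ("ankle", "moment"): flat(0.55),
                ("ankle", "power"): flat(0.45),
                ("knee", "power"): flat(0.85),
            },
            subphase_jitter_sd=2.0,
            trial_noise_sd=0.035,
            subject_offset_sd=0.035,
        ),
        "transfemoral": CohortProfile(
            cohort="transfemoral",
            amplitude_scale={
                ("knee", "power"): flat(0.25),
                ("knee", "moment"): flat(0.30),
                ("knee", "angle"): stance(0.5),
                ("ankle", "power"): flat(0.55),
                ("ankle", "moment"): flat(0.65),
            },
            subphase_jitter_sd=3.0,
            trial_noise_sd=0.045,
            subject_offset_sd=0.045,
        ),
    }


# ---------------------------------------------------------------------------
# Trial generation

_SMOOTH_KERNEL = np.exp(-0.5 * (np.arange(-3, 4) / 1.2) ** 2)
_SMOOTH_KERNEL /= _SMOOTH_KERNEL.sum()


def _smooth_periodic(values: np.ndarray) -> np.ndarray:
    """Circular convolution with a short Gaussian kernel (mean-preserving)."""
    padded = np.concatenate([values[-3:], values, values[:3]])
    return np.convolve(padded, _SMOOTH_KERNEL, mode="same")[3:-3]


def _jittered_labels(rng: np.random.Generator, jitter_sd_pct: float) -> np.ndarray:
    if jitter_sd_pct == 0:
        return canonical_subphase_labels()
    # 1 grid sample = 2% of cycle
    jitter = np.round(rng.normal(0.0, jitter_sd_pct / 2.0, size=6)).astype(int)
    starts = [0]
    for base, dj in zip(CANONICAL_PHASE_STARTS[1:], jitter):
        lo = starts[-1] + 1
        hi = N_SAMPLES - (7 - len(starts))  # leave room for remaining phases
        starts.append(int(np.clip(base + dj, lo, hi)))
    return _labels_from_starts(starts)


def generate_trial(
    profile: CohortProfile,
    template: TemplateBank,
    subject_id: str,
    trial_index: int,
    seed: int | np.random.SeedSequence,
    subject_offsets: Mapping[VarKey, float] | None = None,
    side: str = "left",
) -> GaitTrial:
    """Generate one synthetic stride-normalized trial.

    Deterministic for a fixed seed.  Per-phase amplitude scales and offsets
    follow the trial's own (jittered) sub-phase labels, so a cohort deficit
    stays locked to the sub-phase it belongs to even when boundaries shift.
    """
    if profile.is_degenerate():
        warnings.warn(
            f"profile {profile.cohort!r} scales every variable to zero",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    labels = _jittered_labels(rng, profile.subphase_jitter_sd)
    series: dict[VarKey, np.ndarray] = {}
    for key in VARKEYS:
        base = template.curves[key]
        var_range = template.range(key)
        scale = profile.scale_for(key)[labels - 1]
        offs = profile.offset_for(key)[labels - 1]
        values = base * scale + offs
        if profile.trial_noise_sd > 0:
            noise = rng.normal(0.0, profile.trial_noise_sd * var_range, N_SAMPLES)
            values = values + _smooth_periodic(noise)
        if subject_offsets is not None:
            values = values + subject_offsets.get(key, 0.0)
        series[key] = values
    return GaitTrial(
        subject_id=subject_id,
        cohort=profile.cohort,
        trial_index=trial_index,
        side=side,
        series=series,
        subphase=labels,
    )


def generate_cohort(
    profile: CohortProfile,
    template: TemplateBank,
    n_subjects: int,
    n_trials: int,
    seed: int | np.random.SeedSequence,
    subject_prefix: str | None = None,
) -> list[GaitTrial]:
    """Generate ``n_subjects × n_trials`` trials with shared per-subject offsets.

    All randomness derives deterministically from the master seed via
    spawned :class:`numpy.random.SeedSequence` streams.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    default_prefixes = {
        "normal": "N",
        "transtibial": "TT",
        "transfemoral": "TF",
        "orthosis": "OT",
    }
    prefix = subject_prefix or default_prefixes.get(
        profile.cohort, profile.cohort[:2].upper()
    )
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    subject_seeds = master.spawn(n_subjects)
    trials: list[GaitTrial] = []
    for s_idx, s_seq in enumerate(subject_seeds):
        offset_seq, *trial_seqs = s_seq.spawn(n_trials + 1)
        offset_rng = np.random.default_rng(offset_seq)
        offsets = {
            key: offset_rng.normal(0.0, profile.subject_offset_sd * template.range(key))
            for key in VARKEYS
        }
        subject_id = f"{prefix}{s_idx + 1:02d}"
        for t_idx, t_seq in enumerate(trial_seqs):
            trials.append(
                generate_trial(
                    profile,
                    template,
                    subject_id=subject_id,
                    trial_index=t_idx + 1,
                    seed=t_seq,
                    subject_offsets=offsets,
                )
            )
    return trials
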