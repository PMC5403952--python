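"""Disparity scoring of gait cyclograms with per-pair linear networks.

For each of the 36 cyclogram pairs a small feed-forward network with the
fixed architecture 30 → 7 → 3 and linear activations throughout is trained
to map ten trials of a subject's coupled variables (plus their sub-phase
labels) onto the normal reference curves.  The 50 stride-grid samples are
the observation unit: the input matrix is 30×50 (rows 1–10 the first
variable over 10 trials, rows 11–20 the second variable, rows 21–30 the
sub-phase labels) and the target matrix is 3×50 (the two trial-averaged
normal curves plus the canonical phase signal).

Training follows the acceptance procedure of the original protocol: the 50
columns are split at random into training (60%), validation (20%) and test
(20%) sets; weights are reinitialized (up to ``max_restarts`` times) until
(1) the final normalized training MSE is below 0.9, (2) validation and test
errors are similar, and (3) the regression R on every split exceeds 0.9.

Disparity of a subject is then quantified by simulating their trials
through the accepted network and comparing the predicted curves with the
conventional trial-averaged normal curves: globally via the closeness
statistic ``C = (1 − e_pc) × 100`` and locally via per-sub-phase mean
normalized errors, whose per-phase maximum over the 36 pairs identifies the
worst coupled relationship in each gait sub-phase.

The public surface is statsmodels-shaped: :class:`DisparityModel` is built
from data and ``fit()`` returns a :class:`DisparityResults` carrying the
weights, the training report and prediction/scoring methods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cyclogram import CyclogramPair, NormalReference, enumerate_pairs
from .gaitdata import GaitDataError, GaitTrial, N_SAMPLES, SUBPHASE_NAMES

__all__ = [
    "N_TRIALS_PER_ARRANGEMENT",
    "TrainingArrangement",
    "TrainingCriteria",
    "TrainingReport",
    "DisparityModel",
    "DisparityResults",
    "ClosenessScore",
    "SubPhaseErrorTable",
    "arrange",
    "closeness",
    "subphase_errors",
    "worst_pair_table",
    "train_all_pairs",
]

N_TRIALS_PER_ARRANGEMENT = 10
_HIDDEN = 7
_N_INPUT = 3 * N_TRIALS_PER_ARRANGEMENT
_N_OUTPUT = 3


def _modal_labels(trials: Sequence[GaitTrial]) -> np.ndarray:
    """Pointwise most frequent sub-phase label across a subject's trials."""
    stack = np.stack([t.subphase for t in trials])
    labels = np.empty(N_SAMPLES, dtype=int)
    for i in range(N_SAMPLES):
        values, counts = np.unique(stack[:, i], return_counts=True)
        labels[i] = values[np.argmax(counts)]
    return np.maximum.accumulate(labels)


@dataclass
class TrainingArrangement:
    """The 30×50 input / 3×50 target layout for one subject and pair."""

    pair: CyclogramPair
    inputs: np.ndarray  # (30, 50) raw units
    targets: np.ndarray  # (3, 50) raw units
    labels: np.ndarray  # (50,) modal sub-phase labels of the subject
    subject_id: str
    a_range: float
    b_range: float
    a_min: float
    b_min: float
    resampled: bool = False

    def __post_init__(self) -> None:
        if self.inputs.shape != (_N_INPUT, N_SAMPLES):
            raise GaitDataError(
                f"inputs must be {_N_INPUT}x{N_SAMPLES}, got {self.inputs.shape}"
            )
        if self.targets.shape != (_N_OUTPUT, N_SAMPLES):
            raise GaitDataError(
                f"targets must be {_N_OUTPUT}x{N_SAMPLES}, got {self.targets.shape}"
            )
        label_rows = self.inputs[2 * N_TRIALS_PER_ARRANGEMENT :]
        if not np.all(np.isin(label_rows, np.arange(1, 8))):
            raise GaitDataError("sub-phase rows must contain integer labels 1..7")

    # -- range normalization: variables to [~0, 1] via the reference
    #    min/range, labels linearly to [0, 1]; makes the MSE<0.9 criterion
    #    comparable across pairs with heterogeneous units.
    def _scale_inputs(self) -> np.ndarray:
        X = self.inputs.copy()
        n = N_TRIALS_PER_ARRANGEMENT
        X[:n] = (X[:n] - self.a_min) / self.a_range
        X[n : 2 * n] = (X[n : 2 * n] - self.b_min) / self.b_range
        X[2 * n :] = (X[2 * n :] - 1.0) / 6.0
        return X

    def _scale_targets(self) -> np.ndarray:
        Y = self.targets.copy()
        Y[0] = (Y[0] - self.a_min) / self.a_range
        Y[1] = (Y[1] - self.b_min) / self.b_range
        Y[2] = (Y[2] - 1.0) / 6.0
        return Y

    def _unscale_outputs(self, P: np.ndarray) -> np.ndarray:
        out = P.copy()
        out[0] = out[0] * self.a_range + self.a_min
        out[1] = out[1] * self.b_range + self.b_min
        out[2] = out[2] * 6.0 + 1.0
        return out


def arrange(
    trials: Sequence[GaitTrial],
    pair: CyclogramPair,
    reference: NormalReference,
    allow_resample: bool = False,
    seed: int | None = None,
) -> TrainingArrangement:
    """Stack 10 trials of one subject into the network input/target layout.

    Exactly 10 trials are required; with ``allow_resample=True`` a short
    trial list is resampled with replacement to 10 (seeded) and the
    arrangement is flagged.
    """
    trials = list(trials)
    subjects = {t.subject_id for t in trials}
    if len(subjects) != 1:
        raise GaitDataError(
            f"an arrangement holds one subject's trials, got {sorted(subjects)}"
        )
    resampled = False
    if len(trials) != N_TRIALS_PER_ARRANGEMENT:
        if not allow_resample or len(trials) > N_TRIALS_PER_ARRANGEMENT:
            raise GaitDataError(
                f"expected exactly {N_TRIALS_PER_ARRANGEMENT} trials, got {len(trials)}"
            )
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(trials), N_TRIALS_PER_ARRANGEMENT)
        trials = [trials[i] for i in idx]
        resampled = True
    a = np.stack([t.series[pair.var_a] for t in trials])
    b = np.stack([t.series[pair.var_b] for t in trials])
    phases = np.stack([t.subphase.astype(float) for t in trials])
    inputs = np.vstack([a, b, phases])
    targets = np.vstack(
        [
            reference.curve(pair.var_a),
            reference.curve(pair.var_b),
            reference.subphase.astype(float),
        ]
    )
    return TrainingArrangement(
        pair=pair,
        inputs=inputs,
        targets=targets,
        labels=_modal_labels(trials),
        subject_id=trials[0].subject_id,
        a_range=reference.ranges[pair.var_a],
        b_range=reference.ranges[pair.var_b],
        a_min=float(reference.curve(pair.var_a).min()),
        b_min=float(reference.curve(pair.var_b).min()),
        resampled=resampled,
    )


@dataclass
class TrainingCriteria:
    """Acceptance thresholds for a trained network.

    ``mse_max``: final training MSE bound on range-normalized data.
    ``r_min``: minimum regression R (Pearson correlation between flattened
    predictions and targets) on every split.
    ``val_test_ratio``: validation and test errors count as "similar" when
    their absolute difference is at most this fraction of the larger one.
    """

    mse_max: float = 0.9
    r_min: float = 0.9
    val_test_ratio: float = 0.5
    max_epochs: int = 200


@dataclass
class TrainingReport:
    """Diagnostics of one accepted (or best failed) training run."""

    final_mse: float
    mse_val: float
    mse_test: float
    r_train: float
    r_val: float
    r_test: float
    criteria_passed: dict[str, bool]
    accepted: bool
    n_restarts_used: int
    n_epochs: int
    seed: int | None
    split_sizes: tuple[int, int, int]

    @property
    def min_split_r(self) -> float:
        return min(self.r_train, self.r_val, self.r_test)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x.ravel()
    y = y.ravel()
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


class DisparityModel:
    """A 30-7-3 linear feed-forward disparity network for one cyclogram pair.

    Parameters
    ----------
    arrangements : TrainingArrangement or sequence thereof
        One arrangement per training subject; their 50-column blocks are
        concatenated, and columns (stride-grid samples) are the unit of the
        random 60/20/20 split.
    criteria : TrainingCriteria, optional
        Acceptance thresholds; defaults to the standard protocol.
    """

    def __init__(
        self,
        arrangements: TrainingArrangement | Sequence[TrainingArrangement],
        criteria: TrainingCriteria | None = None,
    ) -> None:
        if isinstance(arrangements, TrainingArrangement):
            arrangements = [arrangements]
        arrangements = list(arrangements)
        if not arrangements:
            raise GaitDataError("at least one training arrangement is required")
        pairs = {a.pair for a in arrangements}
        if len(pairs) != 1:
            raise GaitDataError("all arrangements must describe the same pair")
        self.arrangements = arrangements
        self.pair = arrangements[0].pair
        self.criteria = criteria or TrainingCriteria()
        self._X = np.hstack([a._scale_inputs() for a in arrangements])
        self._Y = np.hstack([a._scale_targets() for a in arrangements])

    @classmethod
    def from_trials(
        cls,
        trials: Sequence[GaitTrial],
        pair: CyclogramPair,
        reference: NormalReference,
        criteria: TrainingCriteria | None = None,
        allow_resample: bool = False,
        seed: int | None = None,
    ) -> "DisparityModel":
        """Build a model from trials, one arrangement per subject."""
        by_subject: dict[str, list[GaitTrial]] = {}
        for t in trials:
            by_subject.setdefault(t.subject_id, []).append(t)
        arrangements = [
            arrange(sub_trials, pair, reference, allow_resample=allow_resample, seed=seed)
            for sub_trials in by_subject.values()
        ]
        return cls(arrangements, criteria=criteria)

    # -- optimization -----------------------------------------------------
    @staticmethod
    def _pack(W1, b1, W2, b2) -> np.ndarray:
        return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])

    @staticmethod
    def _unpack(theta: np.ndarray) -> tuple[np.ndarray, ...]:
        i = 0
        W1 = theta[i : i + _HIDDEN * _N_INPUT].reshape(_HIDDEN, _N_INPUT)
        i += _HIDDEN * _N_INPUT
        b1 = theta[i : i + _HIDDEN]
        i += _HIDDEN
        W2 = theta[i : i + _N_OUTPUT * _HIDDEN].reshape(_N_OUTPUT, _HIDDEN)
        i += _N_OUTPUT * _HIDDEN
        b2 = theta[i : i + _N_OUTPUT]
        return W1, b1, W2, b2

    def _train_once(
        self,
        rng: np.random.Generator,
        train_idx: np.ndarray,
    ) -> tuple[list[np.ndarray], float, int]:
        """Levenberg-Marquardt backpropagation on the training columns.

        The Jacobian of the residuals with respect to all 241 weights and
        biases is exact (the network is linear), so each damped
        Gauss-Newton step solves the local quadratic model directly —
        the standard trainer for small feed-forward networks, and the
        only one that reliably resolves the near-collinear trial rows.
        """
        X, Y = self._X[:, train_idx], self._Y[:, train_idx]
        n = X.shape[1]
        W1 = rng.normal(0.0, np.sqrt(1.0 / _N_INPUT), (_HIDDEN, _N_INPUT))
        b1 = np.zeros(_HIDDEN)
        W2 = rng.normal(0.0, np.sqrt(1.0 / _HIDDEN), (_N_OUTPUT, _HIDDEN))
        b2 = np.zeros(_N_OUTPUT)

        def residual(W1, b1, W2, b2):
            H = W1 @ X + b1[:, None]
            P = W2 @ H + b2[:, None]
            return P - Y, H

        R, H = residual(W1, b1, W2, b2)
        sse = float(np.sum(R**2))
        mu = 1e-3
        epoch = 0
        for epoch in range(1, self.criteria.max_epochs + 1):
            # Jacobian of vec(P) (order: output o outer, column s inner)
            J1 = np.einsum("oh,is->oshi", W2, X).reshape(_N_OUTPUT * n, -1)
            J2 = np.broadcast_to(W2[:, None, :], (_N_OUTPUT, n, _HIDDEN)).reshape(
                _N_OUTPUT * n, _HIDDEN
            )
            J3 = np.zeros((_N_OUTPUT, n, _N_OUTPUT, _HIDDEN))
            for o in range(_N_OUTPUT):
                J3[o, :, o, :] = H.T
            J3 = J3.reshape(_N_OUTPUT * n, _N_OUTPUT * _HIDDEN)
            J4 = np.zeros((_N_OUTPUT, n, _N_OUTPUT))
            for o in range(_N_OUTPUT):
                J4[o, :, o] = 1.0
            J4 = J4.reshape(_N_OUTPUT * n, _N_OUTPUT)
            J = np.hstack([J1, J2, J3, J4])
            r = R.reshape(-1)
            g = J.T @ r
            if np.max(np.abs(g)) < 1e-12:
                break
            JTJ = J.T @ J
            theta = self._pack(W1, b1, W2, b2)
            stepped = False
            while mu <= 1e10:
                try:
                    delta = np.linalg.solve(
                        JTJ + mu * np.eye(len(theta)), g
                    )
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                cand = self._unpack(theta - delta)
                R_new, H_new = residual(*cand)
                sse_new = float(np.sum(R_new**2))
                if sse_new < sse:
                    W1, b1, W2, b2 = cand
                    R, H = R_new, H_new
                    improvement = sse - sse_new
                    sse = sse_new
                    mu = max(mu * 0.3, 1e-12)
                    stepped = True
                    break
                mu *= 10.0
            if not stepped or sse <= 1e-28 or improvement < 1e-16 * max(sse, 1e-30):
                break
        mse = sse / R.size
        return [W1, b1, W2, b2], mse, epoch

    def _split(
        self, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self._X.shape[1]
        perm = rng.permutation(n)
        n_train = int(round(0.6 * n))
        n_val = int(round(0.2 * n))
        return (
            perm[:n_train],
            perm[n_train : n_train + n_val],
            perm[n_train + n_val :],
        )

    def fit(
        self, seed: int | None = None, max_restarts: int = 10
    ) -> "DisparityResults":
        """Train with seeded restarts until the acceptance criteria pass.

        Weights are reinitialized (and the 60/20/20 column split redrawn)
        up to ``max_restarts`` times; if no run passes, the best run by
        training MSE is returned with ``report.accepted = False`` — a
        failing network is never returned unflagged.
        """
        if max_restarts < 1:
            raise GaitDataError("max_restarts must be >= 1")
        rng = np.random.default_rng(seed)
        crit = self.criteria
        best: tuple | None = None
        for restart in range(1, max_restarts + 1):
            train_idx, val_idx, test_idx = self._split(rng)
            weights, mse_train, n_epochs = self._train_once(rng, train_idx)
            W1, b1, W2, b2 = weights
            P = W2 @ (W1 @ self._X + b1[:, None]) + b2[:, None]

            def split_stats(idx: np.ndarray) -> tuple[float, float]:
                resid = P[:, idx] - self._Y[:, idx]
                return float(np.mean(resid**2)), _pearson(P[:, idx], self._Y[:, idx])

            mse_val, r_val = split_stats(val_idx)
            mse_test, r_test = split_stats(test_idx)
            _, r_train = split_stats(train_idx)
            passed = {
                "final_mse_lt_max": mse_train < crit.mse_max,
                "val_test_similar": abs(mse_test - mse_val)
                <= crit.val_test_ratio * max(mse_test, mse_val, 1e-30),
                "regression_all_splits": min(r_train, r_val, r_test) > crit.r_min,
            }
            report = TrainingReport(
                final_mse=mse_train,
                mse_val=mse_val,
                mse_test=mse_test,
                r_train=r_train,
                r_val=r_val,
                r_test=r_test,
                criteria_passed=passed,
                accepted=all(passed.values()),
                n_restarts_used=restart,
                n_epochs=n_epochs,
                seed=seed,
                split_sizes=(len(train_idx), len(val_idx), len(test_idx)),
            )
            candidate = (weights, report, train_idx)
            if report.accepted:
                best = candidate
                break
            if best is None or mse_train < best[1].final_mse:
                best = candidate
        weights, report, train_idx = best
        if not report.accepted:
            warnings.warn(
                f"network for pair {self.pair.label} failed acceptance after "
                f"{max_restarts} restarts (MSE={report.final_mse:.3g})",
                stacklevel=2,
            )
        return DisparityResults(
            model=self,
            pair=self.pair,
            weights=weights,
            report=report,
            train_columns=train_idx,
        )


@dataclass
class ClosenessScore:
    """The closeness statistic ``C = (1 − e_pc) × 100``.

    ``e_pc`` is the mean normalized point error between the predicted and
    the conventional trial-averaged curves (0 = no error, 1 = maximal).
    """

    C: float
    e_pc: float


def closeness(
    predicted: np.ndarray,
    conventional: np.ndarray,
    ranges: Sequence[float],
) -> ClosenessScore:
    """Score how close predicted curves are to the conventional curves.

    Per-point absolute errors are normalized by each variable's reference
    range, clipped at 1 (one full range = 100% error), and averaged over
    both variables and all grid points.
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    conventional = np.atleast_2d(np.asarray(conventional, dtype=float))
    ranges_arr = np.asarray(ranges, dtype=float)
    if np.any(ranges_arr <= 0):
        raise GaitDataError("normalization ranges must be positive")
    err = np.abs(predicted - conventional) / ranges_arr[:, None]
    e_pc = float(np.clip(err, 0.0, 1.0).mean())
    return ClosenessScore(C=(1.0 - e_pc) * 100.0, e_pc=e_pc)


def subphase_errors(
    predicted: np.ndarray,
    target: np.ndarray,
    labels: np.ndarray,
    ranges: Sequence[float],
) -> np.ndarray:
    """Per-sub-phase mean normalized error of two predicted curves.

    For each sub-phase ``s`` the absolute errors at samples labeled ``s``,
    normalized by each variable's reference range, are averaged over both
    variable rows.  Sub-phases with no labeled sample are NaN (flagged
    missing rather than zero).
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    labels = np.asarray(labels)
    ranges_arr = np.asarray(ranges, dtype=float)
    if np.any(ranges_arr <= 0):
        raise GaitDataError("normalization ranges must be positive")
    err = np.abs(predicted - target) / ranges_arr[:, None]
    out = np.full(7, np.nan)
    for phase in range(1, 8):
        mask = labels == phase
        if mask.any():
            out[phase - 1] = float(err[:, mask].mean())
    return out


@dataclass
class DisparityResults:
    """Fitted disparity network plus its training diagnostics."""

    model: DisparityModel
    pair: CyclogramPair
    weights: list[np.ndarray]
    report: TrainingReport
    train_columns: np.ndarray = field(repr=False)

    # -- linear algebra ---------------------------------------------------
    def equivalent_linear_map(self) -> tuple[np.ndarray, np.ndarray]:
        """The composed 3×30 linear map ``x -> A x + c`` of the network.

        With linear activations the 30→7→3 network collapses to a single
        affine map of rank ≤ min(7, 3) = 3.
        """
        W1, b1, W2, b2 = self.weights
        return W2 @ W1, W2 @ b1 + b2

    def _forward_scaled(self, X: np.ndarray) -> np.ndarray:
        A, c = self.equivalent_linear_map()
        return A @ X + c[:, None]

    # -- prediction -------------------------------------------------------
    def predict_arrangement(self, arr: TrainingArrangement) -> np.ndarray:
        """Forward pass on an arrangement; (3, 50) output in raw units."""
        if arr.pair != self.pair:
            raise GaitDataError(
                f"arrangement pair {arr.pair.label} does not match "
                f"network pair {self.pair.label}"
            )
        P = self._forward_scaled(arr._scale_inputs())
        return arr._unscale_outputs(P)

    def simulate(
        self,
        subject_trials: Sequence[GaitTrial],
        reference: NormalReference,
        allow_resample: bool = False,
        seed: int | None = None,
    ) -> tuple[np.ndarray, TrainingArrangement]:
        """Arrange a subject's trials and predict; returns (output, arrangement)."""
        arr = arrange(
            subject_trials,
            self.pair,
            reference,
            allow_resample=allow_resample,
            seed=seed,
        )
        return self.predict_arrangement(arr), arr

    def closeness(
        self,
        subject_trials: Sequence[GaitTrial],
        reference: NormalReference,
        **kwargs,
    ) -> ClosenessScore:
        """Closeness C of a subject's predicted curves to the normal curves."""
        pred, arr = self.simulate(subject_trials, reference, **kwargs)
        return closeness(
            pred[:2], arr.targets[:2], ranges=(arr.a_range, arr.b_range)
        )

    def subphase_errors(
        self,
        subject_trials: Sequence[GaitTrial],
        reference: NormalReference,
        **kwargs,
    ) -> np.ndarray:
        """Per-sub-phase mean normalized errors (unitless) for a subject."""
        pred, arr = self.simulate(subject_trials, reference, **kwargs)
        return subphase_errors(
            pred[:2], arr.targets[:2], arr.labels, ranges=(arr.a_range, arr.b_range)
        )

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        r = self.report
        lines = [
            f"Disparity network  pair={self.pair.label}  architecture=30-7-3 (linear)",
            "=" * 66,
            f"accepted: {r.accepted}   restarts used: {r.n_restarts_used}"
            f"   epochs: {r.n_epochs}",
            f"final training MSE (normalized): {r.final_mse:.6f}"
            f"   (criterion: < {self.model.criteria.mse_max})",
            f"MSE val/test: {r.mse_val:.6f} / {r.mse_test:.6f}",
            f"regression R  train={r.r_train:.4f}  val={r.r_val:.4f}"
            f"  test={r.r_test:.4f}   (criterion: > {self.model.criteria.r_min})",
            f"split sizes (train/val/test): {r.split_sizes}",
            "criteria: "
            + ", ".join(f"{k}={'pass' if v else 'FAIL'}" for k, v in r.criteria_passed.items()),
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        W1, b1, W2, b2 = self.weights
        payload = {
            "pair": {
                "var_a": list(self.pair.var_a),
                "var_b": list(self.pair.var_b),
                "group": self.pair.group,
            },
            "weights": {
                "W1": W1.tolist(),
                "b1": b1.tolist(),
                "W2": W2.tolist(),
                "b2": b2.tolist(),
            },
            "report": {
                **{
                    k: getattr(self.report, k)
                    for k in (
                        "final_mse",
                        "mse_val",
                        "mse_test",
                        "r_train",
                        "r_val",
                        "r_test",
                        "accepted",
                        "n_restarts_used",
                        "n_epochs",
                        "seed",
                    )
                },
                "criteria_passed": self.report.criteria_passed,
                "split_sizes": list(self.report.split_sizes),
            },
            "train_columns": self.train_columns.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(
        cls,
        path: str | Path,
        model: DisparityModel | None = None,
    ) -> "DisparityResults":
        payload = json.loads(Path(path).read_text())
        p = payload["pair"]
        pair = CyclogramPair(tuple(p["var_a"]), tuple(p["var_b"]), p["group"])
        w = payload["weights"]
        weights = [
            np.asarray(w["W1"]),
            np.asarray(w["b1"]),
            np.asarray(w["W2"]),
            np.asarray(w["b2"]),
        ]
        rep = payload["report"]
        report = TrainingReport(
            final_mse=rep["final_mse"],
            mse_val=rep["mse_val"],
            mse_test=rep["mse_test"],
            r_train=rep["r_train"],
            r_val=rep["r_val"],
            r_test=rep["r_test"],
            criteria_passed=rep["criteria_passed"],
            accepted=rep["accepted"],
            n_restarts_used=rep["n_restarts_used"],
            n_epochs=rep["n_epochs"],
            seed=rep["seed"],
            split_sizes=tuple(rep["split_sizes"]),
        )
        return cls(
            model=model,
            pair=pair,
            weights=weights,
            report=report,
            train_columns=np.asarray(payload["train_columns"], dtype=int),
        )


@dataclass
class SubPhaseErrorTable:
    """Per-(pair, sub-phase) mean normalized errors for one subject.

    Errors are stored ×100 for readability (the scale of the published
    per-phase error tables); ``argmax`` maps each sub-phase (1..7) to the
    index (into ``pairs``) of the pair with the largest error, ties broken
    by canonical pair order.
    """

    subject_id: str
    pairs: list[CyclogramPair]
    errors: np.ndarray  # (n_pairs, 7), percent
    argmax: dict[int, int]
    excluded: list[CyclogramPair] = field(default_factory=list)

    def argmax_pair(self, subphase: int) -> CyclogramPair:
        return self.pairs[self.argmax[subphase]]

    def error(self, pair: CyclogramPair, subphase: int) -> float:
        return float(self.errors[self.pairs.index(pair), subphase - 1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pair in enumerate(self.pairs):
            for phase in range(1, 8):
                rows.append(
                    {
                        "subject_id": self.subject_id,
                        "pair": pair.label,
                        "subphase": phase,
                        "subphase_name": SUBPHASE_NAMES[phase - 1],
                        "mean_normalized_error": self.errors[i, phase - 1],
                        "is_argmax": self.argmax.get(phase) == i,
                    }
                )
        return pd.DataFrame(rows)


def worst_pair_table(
    subject_trials: Sequence[GaitTrial],
    networks: Mapping[CyclogramPair, DisparityResults],
    reference: NormalReference,
    allow_resample: bool = False,
    seed: int | None = None,
) -> SubPhaseErrorTable:
    """Per-sub-phase errors of one subject across all trained networks.

    Networks that failed acceptance are excluded (with a warning) rather
    than silently contributing; the per-phase argmax pair is recorded with
    the canonical-order tie-break.
    """
    pairs = [p for p in networks]
    errors = np.full((len(pairs), 7), np.nan)
    excluded: list[CyclogramPair] = []
    subject_id = subject_trials[0].subject_id
    for i, pair in enumerate(pairs):
        res = networks[pair]
        if not res.report.accepted:
            warnings.warn(
                f"excluding unaccepted network {pair.label} from worst-pair table",
                stacklevel=2,
            )
            excluded.append(pair)
            continue
        errors[i] = (
            res.subphase_errors(
                subject_trials, reference, allow_resample=allow_resample, seed=seed
            )
            * 100.0
        )
    argmax: dict[int, int] = {}
    for phase in range(1, 8):
        col = errors[:, phase - 1]
        if np.all(np.isnan(col)):
            continue
        best = np.nanmax(col)
        # first pair in canonical order attaining the maximum
        argmax[phase] = int(np.flatnonzero(col == best)[0])
    return SubPhaseErrorTable(
        subject_id=subject_id,
        pairs=pairs,
        errors=errors,
        argmax=argmax,
        excluded=excluded,
    )


def train_all_pairs(
    trials: Sequence[GaitTrial],
    reference: NormalReference,
    seed: int,
    pairs: Iterable[CyclogramPair] | None = None,
    criteria: TrainingCriteria | None = None,
    max_restarts: int = 10,
) -> dict[CyclogramPair, DisparityResults]:
    """Fit one disparity network per cyclogram pair on normal training trials.

    Per-pair seeds are spawned deterministically from the master seed.
    """
    pairs = list(pairs) if pairs is not None else enumerate_pairs()
    seeds = np.random.SeedSequence(seed).generate_state(len(pairs)) % (2**31)
    out: dict[CyclogramPair, DisparityResults] = {}
    for pair, pair_seed in zip(pairs, seeds):
        model = DisparityModel.from_trials(trials, pair, reference, criteria=criteria)
        out[pair] = model.fit(seed=int(pair_seed), max_restarts=max_restarts)
    return out
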