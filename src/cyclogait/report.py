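"""Pipeline orchestration and report rendering.

``run_pipeline`` chains the stages — synthetic cohort generation (unless a
trials file is supplied), normal-reference averaging, training of the 36
disparity networks, per-subject disparity scoring, variable manipulation —
and writes every intermediate artifact under the configured output
directory.  ``render_report`` turns the results into human-readable tables
(per-cohort closeness ranges, per-subject worst pairs, dominance full and
knee-only) and optional cyclogram overlay figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .cyclogram import (
    CyclogramPair,
    NormalReference,
    average_reference,
    build_cyclogram,
    enumerate_pairs,
)
from .disparity import (
    DisparityResults,
    SubPhaseErrorTable,
    train_all_pairs,
    worst_pair_table,
)
from .gaitdata import GaitTrial, read_trials, write_trials, SUBPHASE_NAMES
from .manipulate import (
    DominanceResult,
    aggregate_dominance,
    evaluate_candidates,
    restrict_to_knee,
    select_dominant,
)
from .synth import default_templates, generate_cohort

__all__ = ["PipelineResults", "run_pipeline", "render_report", "plot_cyclogram"]

logger = logging.getLogger("cyclogait")

COHORT_ORDER = ("normal", "orthosis", "transtibial", "transfemoral")


@dataclass
class PipelineResults:
    """Everything a full three-phase run produced."""

    config: PipelineConfig
    reference: NormalReference
    networks: dict[CyclogramPair, DisparityResults]
    closeness: pd.DataFrame  # subject_id, cohort, C
    worst_tables: dict[str, SubPhaseErrorTable]
    dominance: dict[str, DominanceResult] = field(default_factory=dict)
    dominance_knee: dict[str, DominanceResult] = field(default_factory=dict)


def _group_by_subject(trials: list[GaitTrial]) -> dict[str, list[GaitTrial]]:
    out: dict[str, list[GaitTrial]] = {}
    for t in trials:
        out.setdefault(t.subject_id, []).append(t)
    return out


def subject_closeness(
    subject_trials: list[GaitTrial],
    networks: dict[CyclogramPair, DisparityResults],
    reference: NormalReference,
) -> float:
    """Subject-level closeness C: mean over all accepted pair networks."""
    scores = [
        res.closeness(subject_trials, reference).C
        for res in networks.values()
        if res.report.accepted
    ]
    return float(np.mean(scores))


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Execute generate -> reference -> train(36) -> disparity -> manipulate.

    Deterministic for a fixed config: all randomness is spawned from
    ``config.seed`` and each stage logs what it drew.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    gen_seed, train_seed = (int(s) for s in master.generate_state(2) % (2**31))

    # -- stage: data -------------------------------------------------------
    if config.trials_path:
        logger.info("stage=load trials=%s", config.trials_path)
        trials = read_trials(config.trials_path)
    else:
        logger.info("stage=generate seed=%d", gen_seed)
        templates = default_templates()
        profiles = config.cohort_profiles()
        trials = []
        cohort_seeds = np.random.SeedSequence(gen_seed).spawn(len(COHORT_ORDER) + 1)
        for cohort, seq in zip(COHORT_ORDER, cohort_seeds):
            n_subj = (
                config.n_normal_subjects
                if cohort == "normal"
                else config.n_subjects_per_cohort
            )
            trials += generate_cohort(
                profiles[cohort], templates, n_subj, config.n_trials, seq
            )
        write_trials(trials, out_dir / "trials.csv")
    trials = [t for t in trials if t.side == config.side]

    normal_trials = [t for t in trials if t.cohort == "normal"]
    patho_trials = [t for t in trials if t.cohort != "normal"]

    # -- stage: reference --------------------------------------------------
    logger.info("stage=reference n_trials=%d", len(normal_trials))
    reference = average_reference(normal_trials)
    reference.to_files(out_dir / "reference.csv", out_dir / "reference.json")

    # -- stage: train 36 networks -----------------------------------------
    from .disparity import TrainingCriteria

    criteria = TrainingCriteria(
        mse_max=config.mse_max,
        r_min=config.r_min,
        val_test_ratio=config.val_test_ratio,
    )
    logger.info("stage=train seed=%d pairs=36", train_seed)
    networks = train_all_pairs(
        normal_trials,
        reference,
        seed=train_seed,
        criteria=criteria,
        max_restarts=config.max_restarts,
    )
    net_dir = out_dir / "networks"
    net_dir.mkdir(exist_ok=True)
    for pair, res in networks.items():
        res.to_json(net_dir / f"{pair.label}.json")
        logger.info(
            "trained pair=%s accepted=%s restarts=%d mse=%.4g",
            pair.label,
            res.report.accepted,
            res.report.n_restarts_used,
            res.report.final_mse,
        )

    # -- stage: disparity --------------------------------------------------
    rows = []
    worst_tables: dict[str, SubPhaseErrorTable] = {}
    for subject_id, sub_trials in _group_by_subject(trials).items():
        C = subject_closeness(sub_trials, networks, reference)
        rows.append(
            {"subject_id": subject_id, "cohort": sub_trials[0].cohort, "C": C}
        )
        if sub_trials[0].cohort != "normal":
            worst_tables[subject_id] = worst_pair_table(
                sub_trials, networks, reference
            )
    closeness_frame = pd.DataFrame(rows)
    closeness_frame.to_csv(out_dir / "closeness.csv", index=False)
    if worst_tables:
        pd.concat([t.to_frame() for t in worst_tables.values()]).to_csv(
            out_dir / "subphase_errors.csv", index=False
        )

    # -- stage: manipulate -------------------------------------------------
    dominance: dict[str, DominanceResult] = {}
    dominance_knee: dict[str, DominanceResult] = {}
    patho_by_subject = _group_by_subject(patho_trials)
    for subject_id, table in worst_tables.items():
        experiments = evaluate_candidates(
            patho_by_subject[subject_id], table, networks, reference
        )
        if not experiments:
            continue
        dom = select_dominant(experiments, tolerance=config.tie_tolerance)
        dominance[subject_id] = dom
        dominance_knee[subject_id] = restrict_to_knee(
            dom, table, tolerance=config.tie_tolerance
        )
    if dominance:
        pd.concat([d.to_frame() for d in dominance.values()]).to_csv(
            out_dir / "dominance.csv", index=False
        )
        pd.concat([d.to_frame() for d in dominance_knee.values()]).to_csv(
            out_dir / "dominance_knee.csv", index=False
        )

    return PipelineResults(
        config=config,
        reference=reference,
        networks=networks,
        closeness=closeness_frame,
        worst_tables=worst_tables,
        dominance=dominance,
        dominance_knee=dominance_knee,
    )


def render_report(results: PipelineResults) -> str:
    """Human-readable summary: closeness ranges, worst pairs, dominance."""
    lines = ["Cyclogram gait-disparity report", "=" * 40, ""]

    lines.append("Closeness to normal (C, %) by cohort")
    lines.append("-" * 40)
    cl = results.closeness
    if cl.empty:
        lines.append("  [missing]")
    else:
        for cohort in COHORT_ORDER:
            grp = cl[cl.cohort == cohort]
            if grp.empty:
                continue
            lines.append(
                f"  {cohort:<13s} n={len(grp):<3d} "
                f"range {grp.C.min():.1f}-{grp.C.max():.1f}%  "
                f"median {grp.C.median():.1f}%"
            )
    lines.append("")

    lines.append("Trained networks: "
                 f"{sum(r.report.accepted for r in results.networks.values())}"
                 f"/{len(results.networks)} accepted")
    lines.append("")

    lines.append("Worst coupled pair per gait sub-phase")
    lines.append("-" * 40)
    if not results.worst_tables:
        lines.append("  [not run]")
    for subject_id, table in results.worst_tables.items():
        cells = []
        for phase in range(1, 8):
            if phase in table.argmax:
                pair = table.argmax_pair(phase)
                cells.append(
                    f"{SUBPHASE_NAMES[phase-1]}:{pair.label}"
                    f"({table.error(pair, phase):.1f})"
                )
        lines.append(f"  {subject_id}: " + "  ".join(cells))
    lines.append("")

    for title, dom_map in (
        ("Dominant parameters (all joints)", results.dominance),
        ("Dominant parameters (knee only)", results.dominance_knee),
    ):
        lines.append(title)
        lines.append("-" * 40)
        if not dom_map:
            lines.append("  [not run]")
        else:
            agg = aggregate_dominance(list(dom_map.values()))
            for _, row in agg.iterrows():
                lines.append(f"  {row.subphase_name:<4s} {row.selected}")
        lines.append("")
    return "\n".join(lines)


def plot_cyclogram(
    trial: GaitTrial,
    pair: CyclogramPair,
    reference: NormalReference,
    path: str | Path,
) -> None:
    """Overlay a subject's cyclogram on the normal reference loop (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cyc = build_cyclogram(trial, pair)
    ref_a = reference.curve(pair.var_a)
    ref_b = reference.curve(pair.var_b)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(
        np.append(ref_a, ref_a[0]), np.append(ref_b, ref_b[0]),
        "k-", label="normal reference",
    )
    ax.plot(
        np.append(cyc.a_values, cyc.a_values[0]),
        np.append(cyc.b_values, cyc.b_values[0]),
        "r--", label=cyc.source,
    )
    ax.set_xlabel(" ".join(pair.var_a))
    ax.set_ylabel(" ".join(pair.var_b))
    ax.set_title(pair.label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
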