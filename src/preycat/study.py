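"""Full in-silico study runs: subjects x experiments x treatments.

Each subject plays one pretraining trial, then the five experiments in a
random order; within each experiment the subject is assigned a treatment
(balanced across subjects by default), forages a training trial with
feedback, and immediately takes the fixed, feedback-free test trial.  Learned
state resets between experiments, mirroring the value shuffling that blocks
cross-experiment generalization.  Per-subject RNG streams are derived from
the master seed with a counter scheme, so adding subjects never perturbs
earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from preycat import analysis as _analysis
from preycat import communities as _comm
from preycat.agents import Agent, AgentArchetype, make_subject
from preycat.game import (
    GameConfig,
    run_pretraining,
    run_test_trial,
    run_training_trial,
    trial_score,
)

__all__ = [
    "StudyError",
    "StudyConfig",
    "StudyResult",
    "run_study",
    "write_records",
    "read_records",
    "reproduce_report",
    "RECORD_COLUMNS",
]


class StudyError(ValueError):
    pass


RECORD_COLUMNS = (
    "subject",
    "archetype",
    "experiment",
    "treatment",
    "trial",
    "order",
    "presentation_index",
    "reliable_dimension",
    "reliable_value",
    "reliable_label",
    "reliable_polarity",
    "unreliable_value",
    "unreliable_label",
    "profitability",
    "attacked",
    "outcome",
)


@dataclass
class StudyConfig:
    """Configuration of one simulated study."""

    n_subjects: int = 45
    archetype_mix: dict[str, float] = field(default_factory=lambda: {"humanlike": 1.0})
    archetype_params: dict[str, dict[str, Any]] = field(default_factory=dict)
    master_seed: int = 0
    balance_treatments: bool = True
    trim_for_balance: bool = False
    total_size: int = _comm.DEFAULT_TOTAL_SIZE
    good_abundances: dict[int, tuple[int, ...]] | None = None
    game: GameConfig = field(default_factory=GameConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise StudyError("n_subjects must be >= 1")
        total = sum(self.archetype_mix.values())
        if not self.archetype_mix or abs(total - 1.0) > 1e-9:
            raise StudyError("archetype_mix proportions must sum to 1")
        for kind in self.archetype_mix:
            AgentArchetype(kind)  # validates the name

    @staticmethod
    def from_yaml(path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "game" in raw:
            raw["game"] = GameConfig(**raw["game"])
        if "good_abundances" in raw and raw["good_abundances"] is not None:
            raw["good_abundances"] = {
                int(k): tuple(v) for k, v in raw["good_abundances"].items()
            }
        return StudyConfig(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class StudyResult:
    """Tidy attack records plus per-subject metadata and run manifest."""

    records: pd.DataFrame
    subjects: pd.DataFrame  # subject, archetype, seed info, order, treatments, scores
    config: StudyConfig

    @property
    def n_subjects(self) -> int:
        return int(self.records["subject"].nunique())


def _archetype_sequence(config: StudyConfig) -> list[str]:
    """Deterministic archetype assignment: largest-remainder counts from the
    mix proportions, interleaved round-robin across subjects."""
    kinds = sorted(config.archetype_mix)
    n = config.n_subjects
    quotas = {k: config.archetype_mix[k] * n for k in kinds}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = n - sum(counts.values())
    for k in sorted(kinds, key=lambda k: (-(quotas[k] - counts[k]), k)):
        if leftover == 0:
            break
        counts[k] += 1
        leftover -= 1
    pools = {k: counts[k] for k in kinds}
    seq: list[str] = []
    while len(seq) < n:
        for k in kinds:
            if pools[k] > 0:
                pools[k] -= 1
                seq.append(k)
    return seq[:n]


def run_study(config: StudyConfig | None = None) -> StudyResult:
    """Simulate the whole study: deterministic given the master seed."""
    config = config or StudyConfig()
    master = config.master_seed
    study_rng = np.random.default_rng([master, 0])

    archetypes = _archetype_sequence(config)
    treatments_by_exp = {
        e: _comm.enumerate_treatments(e) for e in _comm.EXPERIMENT_IDS
    }
    treatment_counts = {e: [0, 0, 0, 0] for e in _comm.EXPERIMENT_IDS}

    def community_kwargs(e: int) -> dict:
        kw: dict = {"total_size": config.total_size}
        if config.good_abundances and e in config.good_abundances:
            kw["good_abundances"] = config.good_abundances[e]
        return kw

    all_rows: list[dict] = []
    subject_rows: list[dict] = []
    for idx in range(config.n_subjects):
        subject_id = idx + 1
        kind = archetypes[idx]
        params = config.archetype_params.get(kind, {})
        agent = make_subject(AgentArchetype(kind, params), seed=[master, subject_id, 1])
        runner_rng = np.random.default_rng([master, subject_id, 2])
        order_rng = np.random.default_rng([master, subject_id, 3])

        pre_records = run_pretraining(agent, config.game, runner_rng, subject_id=subject_id)
        agent.reset()

        experiment_order = [int(e) for e in order_rng.permutation(_comm.EXPERIMENT_IDS)]
        assigned: dict[int, int] = {}
        for e in experiment_order:
            if config.balance_treatments:
                counts = treatment_counts[e]
                low = min(counts)
                candidates = [t for t in range(4) if counts[t] == low]
                t = int(candidates[study_rng.integers(len(candidates))])
            else:
                t = int(study_rng.integers(4))
            treatment_counts[e][t] += 1
            assigned[e] = t + 1

        subject_records = list(pre_records)
        scores: dict[int, int] = {}
        for rank, e in enumerate(experiment_order, start=1):
            treatment = treatments_by_exp[e][assigned[e] - 1]
            training = _comm.build_training_community(e, treatment, **community_kwargs(e))
            test = _comm.build_test_community(treatment, config.total_size)
            agent.reset()
            train_recs = run_training_trial(
                training, agent, config.game, runner_rng,
                subject_id=subject_id, order=rank,
            )
            test_recs = run_test_trial(
                test, agent, config.game, runner_rng,
                subject_id=subject_id, order=rank,
            )
            scores[e] = trial_score(train_recs) + trial_score(test_recs)
            subject_records.extend(train_recs)
            subject_records.extend(test_recs)

        for rec in subject_records:
            row = rec.to_row()
            row["archetype"] = kind
            all_rows.append(row)
        subject_rows.append(
            {
                "subject": subject_id,
                "archetype": kind,
                "seed": json.dumps([master, subject_id]),
                "experiment_order": json.dumps(experiment_order),
                "treatments": json.dumps({str(e): assigned[e] for e in experiment_order}),
                "scores": json.dumps({str(e): scores[e] for e in experiment_order}),
            }
        )

    records = pd.DataFrame(all_rows, columns=list(RECORD_COLUMNS))
    result = StudyResult(
        records=records, subjects=pd.DataFrame(subject_rows), config=config
    )
    if config.trim_for_balance:
        result = _trim(result)
    return result


def _trim(result: StudyResult) -> StudyResult:
    """Optional balance trimming: drop surplus (subject, experiment) cells so
    every treatment of every experiment has equal test counts (emulates
    subjects completing fewer than five experiments)."""
    records = result.records
    test = records[(records["trial"] == "test")]
    cell = test.groupby(["experiment", "treatment"])["subject"].nunique()
    target = int(cell.min())
    drop: list[tuple[int, int]] = []
    for (e, t), _n in cell.items():
        subjects = sorted(
            test[(test["experiment"] == e) & (test["treatment"] == t)]["subject"].unique()
        )
        for s in subjects[target:]:
            drop.append((int(s), int(e)))
    if drop:
        mask = ~records.apply(
            lambda r: (int(r["subject"]), int(r["experiment"])) in set(drop), axis=1
        )
        records = records[mask].reset_index(drop=True)
    return StudyResult(records=records, subjects=result.subjects, config=result.config)


# ---------------------------------------------------------------------------
# persistence


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy attack table as CSV (lossless round-trip)."""
    records.to_csv(path, index=False)


def read_records(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a tidy attack-record CSV.

    ``column_map`` renames external columns to the canonical schema (maps
    external name -> canonical name), so deposited data with a different
    layout can be ingested.  Missing required columns raise a schema error
    naming them.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = list(_analysis.REQUIRED_RECORD_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StudyError(f"records file {path} is missing required columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# reporting


def reproduce_report(
    records: pd.DataFrame,
    out_dir: str | Path | None = None,
    alpha: float = 0.05,
    make_plot: bool = False,
    trained_labels=None,
    focal_labels=None,
) -> dict[str, Any]:
    """Run the full analysis and emit the two estimate tables.

    Produces the total-discrimination (sum) and relative-use (difference)
    tables with 95% CIs and Bonferroni letter groups, plus the
    split-vs-lumped likelihood-ratio test.  Writes CSV/JSON (and optionally a
    figure) under ``out_dir`` when given.
    """
    table = _analysis.prepare_table(
        records, trained_labels=trained_labels, focal_labels=focal_labels
    )
    if table["experiment"].nunique() < 2:
        raise StudyError("report requires records from at least two experiments")
    fit = _analysis.fit_model(table)
    report: dict[str, Any] = {"fit": fit, "tables": {}}

    for kind in ("sum", "difference"):
        grouping = _analysis.pairwise_groupings(fit, kind=kind, alpha=alpha)
        rows = []
        for e, res in sorted(grouping.estimates.items()):
            lo, hi = res.ci
            rows.append(
                {
                    "experiment": e,
                    "effect": kind,
                    "estimate": res.estimate,
                    "se": res.se,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "odds_ratio": res.odds_ratio,
                    "group": grouping.letters[e],
                }
            )
        report["tables"][kind] = pd.DataFrame(rows)
        report[f"grouping_{kind}"] = grouping

    try:
        report["lrt"] = _analysis.split_value_lrt(table)
    except _analysis.AnalysisError:
        report["lrt"] = None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for kind, df in report["tables"].items():
            df.to_csv(out / f"contrasts_{kind}.csv", index=False)
        if report["lrt"] is not None:
            (out / "lrt.json").write_text(json.dumps(report["lrt"], indent=2))
        if make_plot:
            _plot_report(report, out / "estimates.png")
    return report


def _plot_report(report: dict[str, Any], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    for ax, kind, title in zip(
        axes, ("sum", "difference"), ("Total discrimination", "Relative use of reliable trait")
    ):
        df = report["tables"][kind]
        ax.errorbar(
            df["experiment"],
            df["estimate"],
            yerr=[df["estimate"] - df["ci_lo"], df["ci_hi"] - df["estimate"]],
            fmt="o",
            capsize=3,
        )
        for _, row in df.iterrows():
            ax.annotate(
                row["group"], (row["experiment"], row["ci_hi"]),
                textcoords="offset points", xytext=(0, 4), ha="center",
            )
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("Experiment")
        ax.set_title(title)
    axes[0].set_ylabel("Log-odds")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
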