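"""Foraging-game mechanics.

A trial presents the prey of a community one at a time, in a random
permutation of the grid (the sequential abstraction of the original on-screen
grid: skipped prey are not revisited).  The agent decides attack/skip for each
prey; in feedback trials the outcome is passed back to the agent and a life
bar rises (+1 for good) or falls (-2 for bad, twice the gain).  Training ends
after half the grid has been attacked, on agent stop, or on death.  The
pretraining trial is all-bad prey with a low starting life bar, and sampling
is compulsory; the test trial gives no feedback and never mutates agent state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

from preycat.communities import CommunitySpec, PreyPhenotype, TraitValue

if TYPE_CHECKING:  # pragma: no cover
    from preycat.agents import Agent

__all__ = [
    "GameConfig",
    "GameState",
    "AttackRecord",
    "GameError",
    "apply_outcome",
    "run_pretraining",
    "run_training_trial",
    "run_test_trial",
    "trial_score",
]


class GameError(RuntimeError):
    pass


@dataclass(frozen=True)
class GameConfig:
    """Payoffs and limits of the game.

    Only the ratios are meaningful: attacking bad prey costs twice what good
    prey yields, the training life bar absorbs eight consecutive bad attacks,
    and the pretraining bar only four.
    """

    grid_size: int = 36
    max_training_attacks: int = 18
    good_gain: int = 1
    bad_loss: int = 2
    training_start_life: int = 16
    pretraining_start_life: int = 8

    def __post_init__(self) -> None:
        if self.bad_loss != 2 * self.good_gain:
            raise GameError("bad_loss must be twice good_gain")
        if self.training_start_life != 8 * self.bad_loss:
            raise GameError("training life bar must absorb exactly 8 bad attacks")
        if self.pretraining_start_life != 4 * self.bad_loss:
            raise GameError("pretraining life bar must absorb exactly 4 bad attacks")
        if not 0 < self.max_training_attacks <= self.grid_size:
            raise GameError("max_training_attacks must be in (0, grid_size]")


@dataclass(frozen=True)
class GameState:
    life: int
    attacks_made: int = 0

    @property
    def alive(self) -> bool:
        return self.life > 0


@dataclass(frozen=True)
class AttackRecord:
    """One predator-prey encounter."""

    subject_id: int
    experiment_id: int
    treatment_id: int
    trial: str  # 'pretraining' | 'training' | 'test'
    order: int  # experiment presentation rank 1..5 (0 for pretraining)
    presentation_index: int  # 1-based position in the presentation sequence
    phenotype: PreyPhenotype
    attacked: bool
    outcome: str  # 'good' | 'bad' | 'not_attacked'

    def __post_init__(self) -> None:
        if (self.outcome == "not_attacked") == self.attacked:
            raise GameError("outcome 'not_attacked' iff attacked is False")

    def to_row(self) -> dict:
        p = self.phenotype
        return {
            "subject": self.subject_id,
            "experiment": self.experiment_id,
            "treatment": self.treatment_id,
            "trial": self.trial,
            "order": self.order,
            "presentation_index": self.presentation_index,
            "reliable_dimension": p.reliable_value.dimension,
            "reliable_value": p.reliable_value.display_name,
            "reliable_label": p.reliable_label,
            "reliable_polarity": p.reliable_polarity,
            "unreliable_value": p.unreliable_value.display_name,
            "unreliable_label": p.unreliable_label,
            "profitability": p.profitability,
            "attacked": self.attacked,
            "outcome": self.outcome,
        }


def apply_outcome(state: GameState, outcome: str, config: GameConfig) -> GameState:
    """Advance the life bar after one attack.

    Life never drops below zero; reaching zero means death.  Life does not
    change between attacks.
    """
    if not state.alive:
        raise GameError("cannot apply an outcome to a dead state")
    if outcome == "good":
        life = state.life + config.good_gain
    elif outcome == "bad":
        life = max(0, state.life - config.bad_loss)
    else:
        raise GameError(f"unknown outcome {outcome!r}")
    return GameState(life=life, attacks_made=state.attacks_made + 1)


_PRETRAIN_PHENOTYPE_CACHE: dict[None, PreyPhenotype] = {}


def _pretraining_phenotype() -> PreyPhenotype:
    """All-bad prey shown only in pretraining (value id 0, never reused)."""
    if None not in _PRETRAIN_PHENOTYPE_CACHE:
        _PRETRAIN_PHENOTYPE_CACHE[None] = PreyPhenotype(
            reliable_index=0,
            reliable_polarity="-",
            unreliable_polarity="-",
            reliable_value=TraitValue("shape", 0, "pretrain-shape"),
            unreliable_value=TraitValue("color", 0, "pretrain-color"),
        )
    return _PRETRAIN_PHENOTYPE_CACHE[None]


def _record(
    *, subject_id: int, experiment_id: int, treatment_id: int, trial: str,
    order: int, index: int, phenotype: PreyPhenotype, attacked: bool, outcome: str,
) -> AttackRecord:
    return AttackRecord(
        subject_id=subject_id,
        experiment_id=experiment_id,
        treatment_id=treatment_id,
        trial=trial,
        order=order,
        presentation_index=index,
        phenotype=phenotype,
        attacked=attacked,
        outcome=outcome,
    )


def run_pretraining(
    agent: "Agent",
    config: GameConfig,
    rng: np.random.Generator | int | None = None,
    *,
    subject_id: int = 0,
) -> list[AttackRecord]:
    """Compulsory-sampling trial on an all-bad grid.

    The agent's decision is overridden to attack (sampling cannot be declined
    and cannot stop early), so the trial always ends at death — after exactly
    ``pretraining_start_life / bad_loss`` attacks — or when the attack cap is
    reached.  Feedback is passed to the agent as in training.
    """
    rng = np.random.default_rng(rng)
    state = GameState(life=config.pretraining_start_life)
    phenotype = _pretraining_phenotype()
    records: list[AttackRecord] = []
    for index in range(1, config.grid_size + 1):
        agent.decide(phenotype)  # decision made, then overridden
        state = apply_outcome(state, "bad", config)
        agent.update(phenotype, "bad")
        records.append(
            _record(
                subject_id=subject_id, experiment_id=0, treatment_id=0,
                trial="pretraining", order=0, index=index,
                phenotype=phenotype, attacked=True, outcome="bad",
            )
        )
        if not state.alive or state.attacks_made >= config.max_training_attacks:
            break
    return records


def run_training_trial(
    community: CommunitySpec,
    agent: "Agent",
    config: GameConfig,
    rng: np.random.Generator | int | None = None,
    *,
    subject_id: int = 0,
    order: int = 1,
) -> list[AttackRecord]:
    """Feedback trial on a training community.

    Prey are presented as a random permutation of the community multiset.
    Every presented prey yields a record; the trial ends at the attack cap,
    death, or an agent stop signal.
    """
    if community.total_size != config.grid_size:
        raise GameError(
            f"community size {community.total_size} != grid size {config.grid_size}"
        )
    rng = np.random.default_rng(rng)
    prey = community.expand()
    perm = rng.permutation(len(prey))
    state = GameState(life=config.training_start_life)
    records: list[AttackRecord] = []
    for index, j in enumerate(perm, start=1):
        phenotype = prey[int(j)]
        attacked = bool(agent.decide(phenotype))
        outcome = phenotype.profitability if attacked else "not_attacked"
        records.append(
            _record(
                subject_id=subject_id,
                experiment_id=community.experiment_id,
                treatment_id=community.treatment.treatment_id,
                trial="training", order=order, index=index,
                phenotype=phenotype, attacked=attacked, outcome=outcome,
            )
        )
        if attacked:
            state = apply_outcome(state, outcome, config)
            agent.update(phenotype, outcome)
            if not state.alive or state.attacks_made >= config.max_training_attacks:
                break
        if agent.wants_stop("training"):
            break
    return records


def run_test_trial(
    test_community: CommunitySpec,
    agent: "Agent",
    config: GameConfig,
    rng: np.random.Generator | int | None = None,
    *,
    subject_id: int = 0,
    order: int = 1,
) -> list[AttackRecord]:
    """Feedback-free trial on the fixed test community.

    Outcomes are recorded for scoring only and are never passed to the agent;
    agent state is asserted unchanged.  The agent may attack any subset and
    stop at any time; there is no attack cap and no death.
    """
    rng = np.random.default_rng(rng)
    prey = test_community.expand()
    perm = rng.permutation(len(prey))
    fingerprint = agent.state_fingerprint()
    records: list[AttackRecord] = []
    for index, j in enumerate(perm, start=1):
        phenotype = prey[int(j)]
        attacked = bool(agent.decide(phenotype))
        outcome = phenotype.profitability if attacked else "not_attacked"
        records.append(
            _record(
                subject_id=subject_id,
                experiment_id=test_community.experiment_id,
                treatment_id=test_community.treatment.treatment_id,
                trial="test", order=order, index=index,
                phenotype=phenotype, attacked=attacked, outcome=outcome,
            )
        )
        if agent.wants_stop("test"):
            break
    if agent.state_fingerprint() != fingerprint:
        raise GameError("agent state changed during a test trial")
    return records


def trial_score(records: Iterable[AttackRecord]) -> int:
    """Score shown to the subject: good prey attacked minus bad prey attacked."""
    score = 0
    for r in records:
        if r.attacked:
            score += 1 if r.outcome == "good" else -1
    return score
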