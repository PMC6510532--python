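"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from preycat import (
    GameConfig,
    StudyConfig,
    build_test_community,
    build_training_community,
    enumerate_treatments,
    make_subject,
    run_study,
    run_test_trial,
    run_training_trial,
)
from preycat.communities import CommunitySpec, PreyPhenotype


# ---------------------------------------------------------------------------
# simple deterministic agents for game-mechanics tests


class AlwaysAttack:
    def decide(self, phenotype):
        return True

    def update(self, phenotype, outcome):
        pass

    def reset(self):
        pass

    def wants_stop(self, trial):
        return False

    def state_fingerprint(self):
        return ()


class NeverAttack(AlwaysAttack):
    def decide(self, phenotype):
        return False


@pytest.fixture
def always_attack():
    return AlwaysAttack()


@pytest.fixture
def never_attack():
    return NeverAttack()


# ---------------------------------------------------------------------------
# community helpers


def all_bad_community(total_size: int = 36) -> CommunitySpec:
    """Hand-built community of identical bad prey (pretraining-like grid used
    to exercise death mechanics in a training trial)."""
    treatment = enumerate_treatments(1)[0]
    phenotype = PreyPhenotype(
        reliable_index=1,
        reliable_polarity="-",
        unreliable_polarity="-",
        reliable_value=treatment.reliable_value(1, "-"),
        unreliable_value=treatment.unreliable_value("-"),
    )
    return CommunitySpec(
        experiment_id=1,
        treatment=treatment,
        entries=((phenotype, total_size),),
        focal=frozenset([phenotype]),
        kind="training",
    )


# ---------------------------------------------------------------------------
# cohorts and studies (session-scoped: reused across tests)


def run_exp1_cohort(
    archetype: str, n_subjects: int, seed: int, params: dict | None = None
) -> pd.DataFrame:
    """Small single-experiment cohort (training + test on design 1) as a tidy
    record table; cheaper than a full study for replicate-heavy tests."""
    config = GameConfig()
    treatment = enumerate_treatments(1)[0]
    training = build_training_community(1, treatment)
    test = build_test_community(treatment)
    rows = []
    from preycat.agents import AgentArchetype

    for s in range(1, n_subjects + 1):
        agent = make_subject(AgentArchetype(archetype, params or {}), seed=[seed, s, 1])
        rng = np.random.default_rng([seed, s, 2])
        for rec in run_training_trial(training, agent, config, rng, subject_id=s):
            rows.append(rec.to_row())
        for rec in run_test_trial(test, agent, config, rng, subject_id=s):
            rows.append(rec.to_row())
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_study():
    """The default-configured study (45 humanlike subjects, master seed 1)."""
    return run_study(StudyConfig(master_seed=1))


@pytest.fixture(scope="session")
def small_study():
    """Cheaper full-design study for analysis unit tests."""
    return run_study(
        StudyConfig(n_subjects=16, archetype_mix={"humanlike": 1.0}, master_seed=3)
    )


@pytest.fixture(scope="session")
def random_study():
    return run_study(
        StudyConfig(n_subjects=30, archetype_mix={"random": 1.0}, master_seed=5)
    )


# ---------------------------------------------------------------------------
# independent oracles


def grid_search_logit(y: np.ndarray, X: np.ndarray, span: float = 8.0) -> np.ndarray:
    """Brute-force two-parameter Bernoulli-logit MLE by nested grid
    refinement (independent of any model-fitting library)."""
    assert X.shape[1] == 2

    def loglik(b0: float, b1: float) -> float:
        eta = X[:, 0] * b0 + X[:, 1] * b1
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())

    center = np.zeros(2)
    width = span
    for _ in range(8):
        g0 = np.linspace(center[0] - width, center[0] + width, 41)
        g1 = np.linspace(center[1] - width, center[1] + width, 41)
        best, best_ll = None, -np.inf
        for b0 in g0:
            for b1 in g1:
                ll = loglik(b0, b1)
                if ll > best_ll:
                    best, best_ll = (b0, b1), ll
        center = np.array(best)
        width = width / 10.0
    return center


def shannon_entropy(counts) -> float:
    """Plain-arithmetic Shannon entropy of an abundance vector."""
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts if c > 0)
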