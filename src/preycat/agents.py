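"""Synthetic predators: decision-model archetypes standing in for subjects.

Each archetype operationalizes one categorization hypothesis:

``rw_learner``
    Compound-cue associative learner (Rescorla-Wagner).  Both displayed trait
    values share a prediction; each update moves every displayed cue's
    strength toward the outcome asymptote by a fraction of the shared
    prediction error, which produces cue competition: the more valid cue
    captures the association (relative validity).
``key_trait``
    Uses only the binary unreliable trait, tallying good/bad outcomes per
    value — the broad, error-tolerant categorizer.
``memorizer``
    Rote table of whole phenotypes with optional capacity limit and an
    unknown-phenotype default policy.
``random``
    Attacks with probability 0.5 regardless of phenotype.
``humanlike``
    Composite: a capacity-limited table keyed on the reliable value, falling
    back on key-trait tallies for values it has not retained.  With few
    reliable values (or an uneven community concentrating encounters on a few
    values) it behaves like a reliable-trait specialist; as richness grows
    past capacity it degrades into a key-trait categorizer.

These are models of the competing hypotheses, not claims about any particular
real predator; every parameter is exposed.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Any, Hashable, Mapping, Sequence

import numpy as np
import scipy.special

from preycat.communities import PreyPhenotype

__all__ = [
    "Agent",
    "AgentArchetype",
    "RWLearner",
    "KeyTraitAgent",
    "MemorizerAgent",
    "RandomAgent",
    "HumanLikeAgent",
    "ARCHETYPES",
    "make_subject",
]


class Agent(ABC):
    """Decision-model contract used by the game runners.

    ``decide`` may be stochastic (agents own their RNG); ``update`` is called
    only after feedback attacks; ``state_fingerprint`` must change iff
    learnable state changes (it deliberately excludes the RNG position).
    """

    def __init__(self, rng: np.random.Generator | int | None = None) -> None:
        self._rng = np.random.default_rng(rng)

    @abstractmethod
    def decide(self, phenotype: PreyPhenotype) -> bool:
        """Attack (True) or skip (False) the presented prey."""

    @abstractmethod
    def update(self, phenotype: PreyPhenotype, outcome: str) -> None:
        """Incorporate feedback from an attacked prey ('good' or 'bad')."""

    @abstractmethod
    def reset(self) -> None:
        """Forget all learned state (called between experiments)."""

    def wants_stop(self, trial: str) -> bool:
        """Optional early-stop signal; default agents never stop early.

        Skipping every remaining prey is record-equivalent to stopping, and
        keeps test tables balanced, so none of the built-in archetypes stop.
        """
        return False

    def state_fingerprint(self) -> Hashable:
        """Hashable snapshot of learnable state (not the RNG)."""
        return self._fingerprint()

    @abstractmethod
    def _fingerprint(self) -> Hashable: ...

    def _bernoulli(self, p: float) -> bool:
        return bool(self._rng.random() < p)


def _cues(phenotype: PreyPhenotype) -> tuple[str, str]:
    return (phenotype.reliable_label, phenotype.unreliable_label)


class RWLearner(Agent):
    """Rescorla-Wagner compound-cue learner with a sigmoid attack policy.

    The prediction for a prey is the sum of associative strengths over its
    displayed cues; after feedback every displayed cue moves toward the
    outcome asymptote by ``alpha`` times the shared prediction error:

        dV_i = alpha * (lambda_outcome - sum_j V_j)

    Attack probability is ``sigmoid(prediction / temperature)``.  Asymptotes
    default to +1 (good) and -2 (bad), mirroring the payoff asymmetry.
    """

    def __init__(
        self,
        alpha: float = 0.35,
        lambda_good: float = 1.0,
        lambda_bad: float = -2.0,
        temperature: float = 0.25,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        super().__init__(rng)
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.alpha = alpha
        self.lambda_good = lambda_good
        self.lambda_bad = lambda_bad
        self.temperature = temperature
        self.V: dict[str, float] = {}

    def prediction(self, phenotype: PreyPhenotype) -> float:
        return sum(self.V.get(c, 0.0) for c in _cues(phenotype))

    def decide(self, phenotype: PreyPhenotype) -> bool:
        z = self.prediction(phenotype) / self.temperature
        return self._bernoulli(float(scipy.special.expit(z)))

    def update(self, phenotype: PreyPhenotype, outcome: str) -> None:
        lam = self.lambda_good if outcome == "good" else self.lambda_bad
        error = lam - self.prediction(phenotype)
        for c in _cues(phenotype):
            self.V[c] = self.V.get(c, 0.0) + self.alpha * error

    def reset(self) -> None:
        self.V.clear()

    def _fingerprint(self) -> Hashable:
        return tuple(sorted(self.V.items()))


class _TallyMixin:
    """Good/bad tallies with a shared decide-from-net rule."""

    epsilon: float
    _rng: np.random.Generator

    def _net_decision(self, net: int) -> bool:
        if net > 0:
            attack = True
        elif net < 0:
            attack = False
        else:
            return bool(self._rng.random() < 0.5)
        if self.epsilon > 0 and self._rng.random() < self.epsilon:
            return not attack
        return attack


class KeyTraitAgent(_TallyMixin, Agent):
    """Categorizes on the binary unreliable trait alone.

    Keeps good/bad tallies per unreliable value; attacks when the tally is
    net-good, rejects when net-bad, guesses on ties.  ``epsilon`` is a lapse
    rate that flips the decision (keeps simulated data off the boundary of
    complete separation)."""

    def __init__(
        self, epsilon: float = 0.05, rng: np.random.Generator | int | None = None
    ) -> None:
        super().__init__(rng)
        if not 0 <= epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        self.epsilon = epsilon
        self.tallies: dict[str, int] = {}

    def decide(self, phenotype: PreyPhenotype) -> bool:
        return self._net_decision(self.tallies.get(phenotype.unreliable_label, 0))

    def update(self, phenotype: PreyPhenotype, outcome: str) -> None:
        delta = 1 if outcome == "good" else -1
        key = phenotype.unreliable_label
        self.tallies[key] = self.tallies.get(key, 0) + delta

    def reset(self) -> None:
        self.tallies.clear()

    def _fingerprint(self) -> Hashable:
        return tuple(sorted(self.tallies.items()))


class MemorizerAgent(_TallyMixin, Agent):
    """Rote memory of whole phenotypes.

    ``capacity`` bounds how many distinct phenotypes are retained (None =
    unlimited); eviction is least-recently-used by default.  Unknown
    phenotypes fall to the ``unknown_policy``: 'optimistic' attacks,
    'pessimistic' rejects, 'random' guesses.
    """

    def __init__(
        self,
        capacity: int | None = None,
        eviction: str = "lru",
        unknown_policy: str = "random",
        epsilon: float = 0.05,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        super().__init__(rng)
        if capacity is not None and capacity < 1:
            raise ValueError("capacity must be >= 1 or None")
        if eviction not in ("lru", "fifo"):
            raise ValueError("eviction must be 'lru' or 'fifo'")
        if unknown_policy not in ("optimistic", "pessimistic", "random"):
            raise ValueError("unknown_policy must be optimistic/pessimistic/random")
        if not 0 <= epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        self.capacity = capacity
        self.eviction = eviction
        self.unknown_policy = unknown_policy
        self.epsilon = epsilon
        self.table: OrderedDict[tuple[str, str], int] = OrderedDict()
        self.miss_count = 0  # decisions made without a table entry

    @staticmethod
    def _key(phenotype: PreyPhenotype) -> tuple[str, str]:
        return (phenotype.reliable_label, phenotype.unreliable_label)

    def decide(self, phenotype: PreyPhenotype) -> bool:
        # Recency is only refreshed on feedback, never here: decisions must
        # not mutate learnable state (test trials assert this).
        key = self._key(phenotype)
        if key in self.table:
            return self._net_decision(self.table[key])
        self.miss_count += 1
        if self.unknown_policy == "optimistic":
            return True
        if self.unknown_policy == "pessimistic":
            return False
        return self._bernoulli(0.5)

    def update(self, phenotype: PreyPhenotype, outcome: str) -> None:
        key = self._key(phenotype)
        delta = 1 if outcome == "good" else -1
        if key in self.table:
            self.table[key] += delta
            if self.eviction == "lru":
                self.table.move_to_end(key)
            return
        if self.capacity is not None and len(self.table) >= self.capacity:
            self.table.popitem(last=False)  # evict oldest (LRU or FIFO front)
        self.table[key] = delta

    def reset(self) -> None:
        self.table.clear()
        self.miss_count = 0

    def _fingerprint(self) -> Hashable:
        # Sorted so that the fingerprint tracks tallies, not recency order;
        # miss_count is a diagnostic counter, not learnable state.
        return tuple(sorted(self.table.items()))


class RandomAgent(Agent):
    """Attacks with probability 0.5 whatever the prey looks like."""

    def decide(self, phenotype: PreyPhenotype) -> bool:
        return self._bernoulli(0.5)

    def update(self, phenotype: PreyPhenotype, outcome: str) -> None:
        pass

    def reset(self) -> None:
        pass

    def _fingerprint(self) -> Hashable:
        return ()


class HumanLikeAgent(_TallyMixin, Agent):
    """Capacity-limited reliable-value memory with a key-trait fallback.

    Retains good/bad tallies for at most ``capacity`` distinct reliable
    values (LRU).  For a prey whose reliable value is retained and has a
    non-zero net tally, the decision follows the reliable trait; otherwise
    the ``fallback`` policy applies: ``'key'`` consults key-trait
    (unreliable-value) tallies and guesses if those are silent;
    ``'pessimistic'`` attacks unknown prey only with probability ``explore``
    (sampling curiosity), so attacks concentrate on retained — in practice,
    abundant — values; ``'random'`` guesses.
    """

    def __init__(
        self,
        capacity: int = 3,
        epsilon: float = 0.05,
        fallback: str = "key",
        explore: float = 0.25,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        super().__init__(rng)
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        if not 0 <= epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if fallback not in ("key", "pessimistic", "random"):
            raise ValueError("fallback must be 'key', 'pessimistic' or 'random'")
        if not 0 <= explore <= 1:
            raise ValueError("explore must be in [0, 1]")
        self.capacity = capacity
        self.epsilon = epsilon
        self.fallback = fallback
        self.explore = explore
        self.reliable_table: OrderedDict[str, int] = OrderedDict()
        self.key_tallies: dict[str, int] = {}
        self.fallback_count = 0

    def decide(self, phenotype: PreyPhenotype) -> bool:
        rkey = phenotype.reliable_label
        if rkey in self.reliable_table and self.reliable_table[rkey] != 0:
            return self._net_decision(self.reliable_table[rkey])
        self.fallback_count += 1
        if self.fallback == "pessimistic":
            return self._bernoulli(self.explore)
        if self.fallback == "random":
            return self._bernoulli(0.5)
        return self._net_decision(self.key_tallies.get(phenotype.unreliable_label, 0))

    def update(self, phenotype: PreyPhenotype, outcome: str) -> None:
        delta = 1 if outcome == "good" else -1
        rkey = phenotype.reliable_label
        if rkey in self.reliable_table:
            self.reliable_table[rkey] += delta
            self.reliable_table.move_to_end(rkey)
        else:
            if len(self.reliable_table) >= self.capacity:
                self.reliable_table.popitem(last=False)
            self.reliable_table[rkey] = delta
        ukey = phenotype.unreliable_label
        self.key_tallies[ukey] = self.key_tallies.get(ukey, 0) + delta

    def reset(self) -> None:
        self.reliable_table.clear()
        self.key_tallies.clear()
        self.fallback_count = 0

    def _fingerprint(self) -> Hashable:
        return (
            tuple(sorted(self.reliable_table.items())),
            tuple(sorted(self.key_tallies.items())),
        )


ARCHETYPES: dict[str, type[Agent]] = {
    "rw_learner": RWLearner,
    "key_trait": KeyTraitAgent,
    "memorizer": MemorizerAgent,
    "random": RandomAgent,
    "humanlike": HumanLikeAgent,
}


@dataclass(frozen=True)
class AgentArchetype:
    """Named archetype plus constructor parameters."""

    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.kind!r}; known: {sorted(ARCHETYPES)}"
            )


def make_subject(
    archetype: AgentArchetype | str,
    seed: int | Sequence[int] | np.random.Generator | None = None,
) -> Agent:
    """Instantiate a fresh agent for one subject.

    Same archetype and seed give identical behavior streams.  Learned state
    is expected to be reset between experiments by the caller (mirroring the
    value shuffling that blocks generalization across experiments).
    """
    if isinstance(archetype, str):
        archetype = AgentArchetype(archetype)
    cls = ARCHETYPES[archetype.kind]
    return cls(rng=np.random.default_rng(seed), **dict(archetype.params))
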