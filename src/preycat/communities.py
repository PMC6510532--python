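"""Prey community construction.

Each community is a multiset of discrete prey phenotypes.  A phenotype has two
traits, one on each display dimension (shape and color).  One dimension is the
*reliable* trait: its values perfectly predict profitability, so a prey
carrying value ``Ri+`` is always good and ``Ri-`` always bad.  The other
dimension is the *unreliable* trait, binary (``U+`` / ``U-``), which agrees
with profitability only for a fixed fraction of prey (0.78 at the default
community size of 36).

Five training designs vary the richness and evenness of the reliable trait's
values while holding everything else fixed:

====  ========  ========================  ==========
exp   richness  good-class abundances     evenness
====  ========  ========================  ==========
1     2         (18,)                     even
2     4         (9, 9)                    even
3     8         (5, 5, 4, 4)              ~even
4     4         (14, 4)                   uneven
5     8         (12, 2, 2, 2)             uneven
====  ========  ========================  ==========

Bad-class abundances mirror the good class, keeping a 1:1 good:bad ratio.
Designs 2/4 share a phenotype set, as do 3/5; only abundances differ.  The
test community is the same for every design: four reliable values (two good,
two bad) crossed with both unreliable values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CommunityError",
    "TraitValue",
    "PreyPhenotype",
    "TreatmentMap",
    "CommunitySpec",
    "DiversityStats",
    "DEFAULT_TOTAL_SIZE",
    "DEFAULT_GOOD_ABUNDANCES",
    "CONGRUENT_FRACTION",
    "build_training_community",
    "build_test_community",
    "diversity_stats",
    "enumerate_treatments",
]


class CommunityError(ValueError):
    """Raised for invalid community parameters."""


DIMENSIONS = ("shape", "color")

SHAPE_NAMES = (
    "circle", "cross", "square", "diamond",
    "star", "triangle", "pentagon", "hexagon",
)
COLOR_NAMES = (
    "blue", "green", "purple", "cyan",
    "yellow", "red", "orange", "magenta",
)

#: Fraction of prey whose unreliable-trait value matches their profitability.
CONGRUENT_FRACTION = 0.78

DEFAULT_TOTAL_SIZE = 36

#: Per-experiment abundances of the good-class reliable values (bad mirrors).
DEFAULT_GOOD_ABUNDANCES: dict[int, tuple[int, ...]] = {
    1: (18,),
    2: (9, 9),
    3: (5, 5, 4, 4),
    4: (14, 4),
    5: (12, 2, 2, 2),
}

EXPERIMENT_IDS = (1, 2, 3, 4, 5)


@dataclass(frozen=True, order=True)
class TraitValue:
    """A concrete display value on one dimension, e.g. shape 'circle'."""

    dimension: str
    value_id: int
    display_name: str

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise CommunityError(f"unknown dimension {self.dimension!r}")


@dataclass(frozen=True, order=True)
class PreyPhenotype:
    """One prey type: a reliable-trait role plus an unreliable-trait role.

    Profitability is determined by the reliable polarity (``+`` is good), so
    the reliable trait is perfectly valid by construction.  The unreliable
    polarity carries no such guarantee; ``congruent`` marks prey whose
    unreliable value agrees with their profitability.
    """

    reliable_index: int
    reliable_polarity: str  # '+' or '-'
    unreliable_polarity: str  # '+' or '-'
    reliable_value: TraitValue
    unreliable_value: TraitValue

    def __post_init__(self) -> None:
        for pol in (self.reliable_polarity, self.unreliable_polarity):
            if pol not in ("+", "-"):
                raise CommunityError(f"polarity must be '+' or '-', got {pol!r}")

    @property
    def profitability(self) -> str:
        return "good" if self.reliable_polarity == "+" else "bad"

    @property
    def reliable_label(self) -> str:
        return f"R{self.reliable_index}{self.reliable_polarity}"

    @property
    def unreliable_label(self) -> str:
        return f"U{self.unreliable_polarity}"

    @property
    def congruent(self) -> bool:
        return self.unreliable_polarity == self.reliable_polarity


@dataclass(frozen=True)
class TreatmentMap:
    """Assignment of abstract trait roles to concrete display values.

    In two of the four treatments of each experiment, shape is the reliable
    dimension; in the other two, color.  Which concrete values play which
    roles is permuted between treatments (and between experiments) so that
    learned value-outcome pairings do not transfer.
    """

    experiment_id: int
    treatment_id: int
    reliable_dimension: str
    assignment: Mapping[str, TraitValue]  # role label -> display value

    def __post_init__(self) -> None:
        values = list(self.assignment.values())
        if len(set(values)) != len(values):
            raise CommunityError("value_assignment must be a bijection")

    @property
    def unreliable_dimension(self) -> str:
        return "color" if self.reliable_dimension == "shape" else "shape"

    def reliable_value(self, index: int, polarity: str) -> TraitValue:
        return self.assignment[f"R{index}{polarity}"]

    def unreliable_value(self, polarity: str) -> TraitValue:
        return self.assignment[f"U{polarity}"]


@dataclass(frozen=True)
class CommunitySpec:
    """A multiset of prey phenotypes with abundances for one trial grid."""

    experiment_id: int
    treatment: TreatmentMap
    entries: tuple[tuple[PreyPhenotype, int], ...]
    focal: frozenset[PreyPhenotype]
    kind: str = "training"  # 'training' or 'test'

    @property
    def total_size(self) -> int:
        return sum(n for _, n in self.entries)

    @property
    def phenotypes(self) -> tuple[PreyPhenotype, ...]:
        return tuple(p for p, _ in self.entries)

    @property
    def reliable_labels(self) -> frozenset[str]:
        return frozenset(p.reliable_label for p, _ in self.entries)

    @property
    def focal_reliable_labels(self) -> frozenset[str]:
        return frozenset(p.reliable_label for p in self.focal)

    def expand(self) -> list[PreyPhenotype]:
        """Flatten to one phenotype per individual prey."""
        out: list[PreyPhenotype] = []
        for phenotype, n in self.entries:
            out.extend([phenotype] * n)
        return out

    def abundance_by_reliable_value(self) -> dict[str, int]:
        agg: dict[str, int] = {}
        for p, n in self.entries:
            agg[p.reliable_label] = agg.get(p.reliable_label, 0) + n
        return agg

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per phenotype."""
        rows = []
        for p, n in sorted(self.entries):
            rows.append(
                {
                    "experiment": self.experiment_id,
                    "treatment": self.treatment.treatment_id,
                    "kind": self.kind,
                    "reliable_value": p.reliable_value.display_name,
                    "reliable_label": p.reliable_label,
                    "reliable_polarity": p.reliable_polarity,
                    "unreliable_value": p.unreliable_value.display_name,
                    "unreliable_label": p.unreliable_label,
                    "profitability": p.profitability,
                    "abundance": n,
                    "focal": p in self.focal,
                }
            )
        return pd.DataFrame(rows)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_frame().to_dict(orient="records"), sort_keys=False)


@dataclass(frozen=True)
class DiversityStats:
    """Richness/evenness summary of the reliable trait's abundance vector.

    ``effective_richness`` is the exponential of the Shannon entropy of the
    relative abundances (the Hill number of order 1), and evenness is the
    ratio of effective to observed richness, in (0, 1].
    """

    richness: int
    effective_richness: float
    evenness: float


# ---------------------------------------------------------------------------
# treatment enumeration


def _palette(dimension: str) -> tuple[str, ...]:
    return SHAPE_NAMES if dimension == "shape" else COLOR_NAMES


def _make_assignment(
    experiment_id: int, treatment_id: int, reliable_dimension: str
) -> dict[str, TraitValue]:
    # Deterministic permutation keyed by (experiment, treatment) so that no
    # two treatments anywhere share a value assignment.
    rng = np.random.default_rng([904611, experiment_id, treatment_id])
    unreliable_dimension = "color" if reliable_dimension == "shape" else "shape"

    rel_names = _palette(reliable_dimension)
    unrel_names = _palette(unreliable_dimension)
    rel_perm = rng.permutation(len(rel_names))
    unrel_perm = rng.permutation(len(unrel_names))

    assignment: dict[str, TraitValue] = {}
    roles = [f"R{i}{pol}" for pol in "+-" for i in range(1, 5)]
    for k, role in enumerate(roles):
        j = int(rel_perm[k])
        assignment[role] = TraitValue(reliable_dimension, j + 1, rel_names[j])
    for k, role in enumerate(("U+", "U-")):
        j = int(unrel_perm[k])
        assignment[role] = TraitValue(unreliable_dimension, j + 1, unrel_names[j])
    return assignment


def enumerate_treatments(experiment_id: int) -> list[TreatmentMap]:
    """The four treatments of an experiment: two with shape reliable, two
    with color reliable, value roles permuted independently in each."""
    _check_experiment(experiment_id)
    treatments = []
    for treatment_id in (1, 2, 3, 4):
        reliable_dimension = "shape" if treatment_id <= 2 else "color"
        assignment = _make_assignment(experiment_id, treatment_id, reliable_dimension)
        treatments.append(
            TreatmentMap(
                experiment_id=experiment_id,
                treatment_id=treatment_id,
                reliable_dimension=reliable_dimension,
                assignment=assignment,
            )
        )
    for a in treatments:
        for b in treatments:
            if a.treatment_id < b.treatment_id and dict(a.assignment) == dict(b.assignment):
                raise CommunityError("duplicate treatment assignment")  # pragma: no cover
    return treatments


def _check_experiment(experiment_id: int) -> None:
    if experiment_id not in EXPERIMENT_IDS:
        raise CommunityError(
            f"unknown experiment_id {experiment_id!r}; expected one of {EXPERIMENT_IDS}"
        )


# ---------------------------------------------------------------------------
# community construction


def _congruent_count(half: int, total: int) -> int:
    """Number of congruent prey per profitability class.

    The realized congruence fraction must land within one prey of the target
    0.78 of the whole community.
    """
    c = int(round(CONGRUENT_FRACTION * half))
    if abs(2 * c - CONGRUENT_FRACTION * total) > 1.0:
        raise CommunityError(
            f"total_size={total}: cannot realize a congruent-prey fraction of "
            f"{CONGRUENT_FRACTION} within one prey (best is {2 * c}/{total})"
        )
    return c


def _allocate_congruent(abundances: Sequence[int], n_congruent: int) -> list[int]:
    """Split ``n_congruent`` prey across reliable values, proportional to
    abundance; largest-remainder leftovers go to the most abundant values
    first (ties to the lowest index).  Deterministic.

    Each value keeps at least one prey of each unreliable pairing when its
    abundance allows (cap at abundance - 1), so designs sharing reliable
    values also share full phenotype sets.
    """
    half = sum(abundances)
    caps = [a - 1 if a >= 2 else a for a in abundances]
    if n_congruent > sum(caps):
        caps = list(abundances)
    quotas = [n_congruent * a / half for a in abundances]
    base = [min(int(np.floor(q)), cap) for q, cap in zip(quotas, caps)]
    remainder = n_congruent - sum(base)
    order = sorted(range(len(abundances)), key=lambda i: (-abundances[i], i))
    while remainder > 0:
        progressed = False
        for i in order:
            if remainder == 0:
                break
            if base[i] < caps[i]:
                base[i] += 1
                remainder -= 1
                progressed = True
        if not progressed:  # caps exhausted; spill over to raw abundances
            caps = list(abundances)
    if remainder != 0:  # pragma: no cover - guarded by preconditions
        raise CommunityError("could not allocate congruent prey")
    return base


def _class_entries(
    treatment: TreatmentMap,
    abundances: Sequence[int],
    reliable_polarity: str,
    n_congruent: int,
) -> list[tuple[PreyPhenotype, int]]:
    congruent = _allocate_congruent(abundances, n_congruent)
    entries = []
    for i, (a, c) in enumerate(zip(abundances, congruent), start=1):
        for unreliable_polarity, count in (
            (reliable_polarity, c),  # congruent pairing
            ("-" if reliable_polarity == "+" else "+", a - c),
        ):
            if count == 0:
                continue
            phenotype = PreyPhenotype(
                reliable_index=i,
                reliable_polarity=reliable_polarity,
                unreliable_polarity=unreliable_polarity,
                reliable_value=treatment.reliable_value(i, reliable_polarity),
                unreliable_value=treatment.unreliable_value(unreliable_polarity),
            )
            entries.append((phenotype, count))
    return entries


def _pick_focal(entries: Sequence[tuple[PreyPhenotype, int]]) -> frozenset[PreyPhenotype]:
    # Four most abundant phenotypes; ties prefer the congruent pairing, then
    # the lowest reliable-value index.
    ranked = sorted(
        entries,
        key=lambda e: (-e[1], not e[0].congruent, e[0].reliable_index, e[0].reliable_polarity),
    )
    return frozenset(p for p, _ in ranked[:4])


def build_training_community(
    experiment_id: int,
    treatment: TreatmentMap | None = None,
    total_size: int = DEFAULT_TOTAL_SIZE,
    good_abundances: Sequence[int] | None = None,
) -> CommunitySpec:
    """Build the training community for one experiment and treatment.

    Parameters
    ----------
    experiment_id
        Design 1-5 (see module docstring for the abundance structure).
    treatment
        Role-to-display-value mapping; defaults to treatment 1 of the
        experiment.
    total_size
        Number of prey on the grid; must be divisible by 4 so the 1:1
        good:bad ratio and the congruence fraction are realizable.
    good_abundances
        Override for the good-class reliable-value abundances (the bad class
        mirrors it).  Must sum to ``total_size / 2``.
    """
    _check_experiment(experiment_id)
    if treatment is None:
        treatment = enumerate_treatments(experiment_id)[0]
    if total_size <= 0 or total_size % 4 != 0:
        raise CommunityError(f"total_size must be a positive multiple of 4, got {total_size}")

    half = total_size // 2
    if good_abundances is None:
        good_abundances = DEFAULT_GOOD_ABUNDANCES[experiment_id]
        if total_size != DEFAULT_TOTAL_SIZE:
            raise CommunityError(
                "non-default total_size requires explicit good_abundances"
            )
    good_abundances = tuple(int(a) for a in good_abundances)
    if any(a <= 0 for a in good_abundances):
        raise CommunityError("abundances must be positive")
    if sum(good_abundances) != half:
        raise CommunityError(
            f"good_abundances sum to {sum(good_abundances)}, expected {half}"
        )
    if len(good_abundances) > 4:
        raise CommunityError("at most four reliable values per profitability class")

    n_congruent = _congruent_count(half, total_size)
    entries = _class_entries(treatment, good_abundances, "+", n_congruent)
    entries += _class_entries(treatment, good_abundances, "-", n_congruent)
    spec = CommunitySpec(
        experiment_id=experiment_id,
        treatment=treatment,
        entries=tuple(entries),
        focal=_pick_focal(entries),
        kind="training",
    )
    assert spec.total_size == total_size
    return spec


def build_test_community(
    treatment: TreatmentMap, total_size: int = DEFAULT_TOTAL_SIZE
) -> CommunitySpec:
    """The fixed test community: identical for every treatment of an
    experiment up to the treatment's value relabeling.

    Always contains four reliable values (two good, two bad) crossed with
    both unreliable values, with the same congruence structure as training.
    """
    if total_size <= 0 or total_size % 4 != 0:
        raise CommunityError(f"total_size must be a positive multiple of 4, got {total_size}")
    half = total_size // 2
    per_value = half // 2
    if 2 * per_value != half:
        raise CommunityError(f"total_size {total_size} not divisible across 4 reliable values")
    abundances = (per_value, per_value)
    n_congruent = _congruent_count(half, total_size)
    entries = _class_entries(treatment, abundances, "+", n_congruent)
    entries += _class_entries(treatment, abundances, "-", n_congruent)
    return CommunitySpec(
        experiment_id=treatment.experiment_id,
        treatment=treatment,
        entries=tuple(entries),
        focal=_pick_focal(entries),
        kind="test",
    )


# ---------------------------------------------------------------------------
# diversity


def diversity_stats(spec: CommunitySpec) -> DiversityStats:
    """Richness, effective richness (exp of Shannon entropy) and evenness of
    the reliable trait's abundance distribution."""
    abundance = spec.abundance_by_reliable_value()
    if not abundance:
        raise CommunityError("empty community")
    counts = np.asarray(list(abundance.values()), dtype=float)
    p = counts / counts.sum()
    entropy = float(-(p * np.log(p)).sum())
    effective = float(np.exp(entropy))
    richness = len(counts)
    return DiversityStats(
        richness=richness,
        effective_richness=effective,
        evenness=effective / richness,
    )


# ---------------------------------------------------------------------------
# serialization


def communities_frame(total_size: int = DEFAULT_TOTAL_SIZE) -> pd.DataFrame:
    """Long-format table of every training and test community (all five
    experiments, all four treatments)."""
    frames = []
    for experiment_id in EXPERIMENT_IDS:
        for treatment in enumerate_treatments(experiment_id):
            frames.append(
                build_training_community(experiment_id, treatment, total_size).to_frame()
            )
            frames.append(build_test_community(treatment, total_size).to_frame())
    return pd.concat(frames, ignore_index=True)
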