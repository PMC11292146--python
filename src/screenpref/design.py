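"""Choice-experiment design: attribute space, blocked random designs, diagnostics.

A discrete choice experiment (DCE) describes a screening test by a fixed set
of attributes, each taking one of a few levels.  Respondents repeatedly choose
between two hypothetical test profiles and may then opt out of testing
altogether.  This module represents the attribute space, generates blocked
random designs subject to realism prohibitions, embeds a fixed dominant task
used as an internal-validity check, and provides design diagnostics and the
Johnson–Orme minimum sample size.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Attribute",
    "AttributeSpace",
    "Profile",
    "Prohibition",
    "ChoiceTask",
    "Design",
    "CoverageReport",
    "default_space",
    "default_prohibitions",
    "default_fixed_task",
    "generate_design",
    "enumerate_profiles",
    "is_dominant",
    "coverage_report",
    "johnson_orme_min_n",
]


class ConfigurationError(ValueError):
    """Raised when a design specification cannot be satisfied."""


@dataclass(frozen=True)
class Attribute:
    """One attribute of a screening test.

    Parameters
    ----------
    name : str
        Unique attribute name, e.g. ``"cost"``.
    levels : tuple of str
        Ordered level labels.
    reference : str
        The dummy-coding reference level (enters utility at 0).
    ranking : tuple of str or None
        Levels from best to worst when the attribute admits a natural
        betterness order (sensitivity, cost, pain, risk); ``None`` for
        unordered attributes (procedure, recommendation), which must be
        equal for one profile to dominate another.
    """

    name: str
    levels: tuple[str, ...]
    reference: str
    ranking: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"duplicate levels in attribute {self.name!r}")
        if self.reference not in self.levels:
            raise ConfigurationError(
                f"reference {self.reference!r} not a level of {self.name!r}"
            )
        if self.ranking is not None and set(self.ranking) != set(self.levels):
            raise ConfigurationError(
                f"ranking of {self.name!r} must be a permutation of its levels"
            )

    def rank(self, level: str) -> int:
        """Position of ``level`` in the betterness order (0 = best)."""
        if self.ranking is None:
            raise ValueError(f"attribute {self.name!r} is unordered")
        return self.ranking.index(level)


@dataclass(frozen=True)
class AttributeSpace:
    """The full set of attributes defining a choice profile."""

    attributes: tuple[Attribute, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ConfigurationError("attribute names must be unique")

    def __len__(self) -> int:
        return len(self.attributes)

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def n_dummies(self) -> int:
        """Number of non-reference level indicators, sum of (levels - 1)."""
        return sum(len(a.levels) - 1 for a in self.attributes)

    def dummy_names(self) -> list[str]:
        """Column labels ``attr=level`` for every non-reference level."""
        out = []
        for a in self.attributes:
            out.extend(f"{a.name}={lv}" for lv in a.levels if lv != a.reference)
        return out

    def validate_profile(self, profile: "Profile") -> None:
        assigned = {k for k, _ in profile.assignment}
        if assigned != set(self.names):
            raise ValueError(
                f"profile must assign every attribute exactly once; "
                f"got {sorted(assigned)}, expected {sorted(self.names)}"
            )
        d = profile.as_dict
        for a in self.attributes:
            if d[a.name] not in a.levels:
                raise ValueError(
                    f"unknown level {d[a.name]!r} for attribute {a.name!r}"
                )


@dataclass(frozen=True)
class Profile:
    """A hypothetical screening test: one level per attribute."""

    assignment: tuple[tuple[str, str], ...]

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "Profile":
        return cls(tuple(sorted(d.items())))

    @property
    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    def __getitem__(self, attr: str) -> str:
        return self.as_dict[attr]


@dataclass(frozen=True)
class Prohibition:
    """A combination of (attribute, level) pairs that may not co-occur.

    A profile violates the prohibition when *every* clause matches it.
    """

    clauses: frozenset[tuple[str, str]]

    def violated_by(self, profile: Profile) -> bool:
        d = profile.as_dict
        return all(d.get(attr) == level for attr, level in self.clauses)

    def validate(self, space: AttributeSpace) -> None:
        for attr, level in self.clauses:
            if level not in space[attr].levels:  # KeyError if attr unknown
                raise ConfigurationError(
                    f"prohibition references unknown level {level!r} of {attr!r}"
                )


@dataclass(frozen=True)
class ChoiceTask:
    """Two test profiles shown side by side, followed by an opt-out stage."""

    left: Profile
    right: Profile
    is_validity_task: bool = False

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValueError("the two profiles of a task must differ somewhere")


@dataclass(frozen=True)
class Design:
    """A blocked DCE design; every block contains the fixed validity task."""

    space: AttributeSpace
    blocks: tuple[tuple[ChoiceTask, ...], ...]
    fixed_task: ChoiceTask
    prohibitions: tuple[Prohibition, ...]
    seed: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def tasks_per_block(self) -> int:
        return len(self.blocks[0]) if self.blocks else 0

    def all_tasks(self) -> list[ChoiceTask]:
        return [t for block in self.blocks for t in block]


# ---------------------------------------------------------------------------
# Default study configuration
# ---------------------------------------------------------------------------

def default_space() -> AttributeSpace:
    """The six-attribute space of the colorectal-cancer screening DCE.

    Procedure (5 levels, reference = 2-day stool test, the current national
    screening convention), pain (2), sensitivity (4, reference 80% matching
    the stool test), recommendation source (4, reference "neither" to expose
    the effect of each recommender), out-of-pocket cost in Singapore dollars
    (5, reference S$0) and procedural risk (2, reference no risk).
    """
    return AttributeSpace(
        (
            Attribute(
                "procedure",
                ("colonoscopy", "ct_colonography", "stool_2day", "stool_1day", "blood"),
                reference="stool_2day",
            ),
            Attribute(
                "pain",
                ("no_pain", "mild_pain"),
                reference="no_pain",
                ranking=("no_pain", "mild_pain"),
            ),
            Attribute(
                "sensitivity",
                ("100", "95", "80", "60"),
                reference="80",
                ranking=("100", "95", "80", "60"),
            ),
            Attribute(
                "recommendation",
                ("hpb", "doctors", "family_friends", "neither"),
                reference="neither",
            ),
            Attribute(
                "cost",
                ("0", "5", "30", "400", "1000"),
                reference="0",
                ranking=("0", "5", "30", "400", "1000"),
            ),
            Attribute(
                "risk",
                ("no_risk", "1pct_adverse"),
                reference="no_risk",
                ranking=("no_risk", "1pct_adverse"),
            ),
        )
    )


def default_prohibitions() -> list[Prohibition]:
    """Realism constraints: stool-based tests never carry a high price or pain.

    Stool tests are cheap self-administered kits, so profiles combining a
    stool procedure with S$400 or S$1000 cost, or with mild pain, are barred.
    The blood test is deliberately left unrestricted: commercial assays may
    be priced high.
    """
    out = []
    for proc in ("stool_2day", "stool_1day"):
        for cost in ("400", "1000"):
            out.append(
                Prohibition(frozenset({("procedure", proc), ("cost", cost)}))
            )
        out.append(
            Prohibition(frozenset({("procedure", proc), ("pain", "mild_pain")}))
        )
    return out


def default_fixed_task() -> ChoiceTask:
    """The fixed internal-validity task shared by every block.

    The left profile is weakly better on every ordered attribute (higher
    sensitivity, lower cost, no risk) and identical on the unordered ones, so
    a respondent attending to the task should never pick the right profile.
    Both profiles satisfy the default prohibitions (the blood test may carry
    a high cost).
    """
    left = Profile.from_dict(
        {
            "procedure": "blood",
            "pain": "no_pain",
            "sensitivity": "95",
            "recommendation": "hpb",
            "cost": "5",
            "risk": "no_risk",
        }
    )
    right = Profile.from_dict(
        {
            "procedure": "blood",
            "pain": "no_pain",
            "sensitivity": "60",
            "recommendation": "hpb",
            "cost": "400",
            "risk": "1pct_adverse",
        }
    )
    return ChoiceTask(left=left, right=right, is_validity_task=True)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def enumerate_profiles(
    space: AttributeSpace, prohibitions: list[Prohibition] | None = None
) -> list[Profile]:
    """All profiles of the space that satisfy every prohibition."""
    prohibitions = list(prohibitions or [])
    for p in prohibitions:
        p.validate(space)
    out = []
    names = space.names
    for combo in itertools.product(*(a.levels for a in space.attributes)):
        profile = Profile.from_dict(dict(zip(names, combo)))
        if not any(p.violated_by(profile) for p in prohibitions):
            out.append(profile)
    return out


def generate_design(
    space: AttributeSpace | None = None,
    n_blocks: int = 20,
    tasks_per_block: int = 10,
    prohibitions: list[Prohibition] | None = None,
    fixed_task: ChoiceTask | None = None,
    seed: int = 0,
) -> Design:
    """Generate a blocked random design with a fixed validity task.

    Non-fixed tasks pair two profiles drawn uniformly at random from the
    prohibition-satisfying profiles, redrawing until the two differ.  The
    fixed task is placed once in every block at a random position.
    Deterministic given ``seed``.
    """
    if space is None:
        space = default_space()
    if prohibitions is None:
        prohibitions = default_prohibitions()
    if fixed_task is None:
        fixed_task = default_fixed_task()
    if n_blocks < 1 or tasks_per_block < 2:
        raise ValueError("need n_blocks >= 1 and tasks_per_block >= 2")
    for profile in (fixed_task.left, fixed_task.right):
        space.validate_profile(profile)
        if any(p.violated_by(profile) for p in prohibitions):
            raise ConfigurationError("fixed task violates a prohibition")

    legal = enumerate_profiles(space, prohibitions)
    if len(legal) < 2:
        raise ConfigurationError(
            "prohibitions leave fewer than two legal profiles; design unsatisfiable"
        )
    rng = np.random.default_rng(seed)
    blocks = []
    for _ in range(n_blocks):
        tasks: list[ChoiceTask] = []
        for _ in range(tasks_per_block - 1):
            while True:
                i, j = rng.integers(0, len(legal), size=2)
                if legal[i] != legal[j]:
                    break
            tasks.append(ChoiceTask(left=legal[i], right=legal[j]))
        pos = int(rng.integers(0, tasks_per_block))
        tasks.insert(pos, fixed_task)
        blocks.append(tuple(tasks))
    return Design(
        space=space,
        blocks=tuple(blocks),
        fixed_task=fixed_task,
        prohibitions=tuple(prohibitions),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def is_dominant(task: ChoiceTask, space: AttributeSpace) -> bool:
    """True iff one profile weakly dominates the other.

    One profile must be at least as good on every ordered attribute, equal on
    every unordered attribute, and strictly better somewhere.  Unordered
    attributes (procedure, recommendation) admit no betterness comparison, so
    any difference there rules dominance out.
    """
    space.validate_profile(task.left)
    space.validate_profile(task.right)

    def dominates(a: Profile, b: Profile) -> bool:
        strict = False
        for attr in space.attributes:
            la, lb = a[attr.name], b[attr.name]
            if attr.ranking is None:
                if la != lb:
                    return False
            else:
                ra, rb = attr.rank(la), attr.rank(lb)
                if ra > rb:
                    return False
                if ra < rb:
                    strict = True
        return strict

    return dominates(task.left, task.right) or dominates(task.right, task.left)


@dataclass
class CoverageReport:
    """Level-appearance and two-way co-occurrence counts for a design."""

    level_counts: dict[tuple[str, str], int]
    pair_counts: dict[tuple[tuple[str, str], tuple[str, str]], int]
    estimable: bool
    missing_levels: list[tuple[str, str]] = field(default_factory=list)


def coverage_report(design: Design) -> CoverageReport:
    """Count level appearances and check that all dummies are estimable.

    Estimability requires every non-reference level to appear at least once
    and the dummy design matrix over all profiles to have full column rank.
    """
    tasks = design.all_tasks()
    if not tasks:
        raise ValueError("design has no tasks")
    space = design.space
    level_counts: dict[tuple[str, str], int] = {
        (a.name, lv): 0 for a in space.attributes for lv in a.levels
    }
    pair_counts: dict[tuple[tuple[str, str], tuple[str, str]], int] = {}
    rows = []
    for task in tasks:
        for profile in (task.left, task.right):
            items = sorted(profile.assignment)
            for key in items:
                level_counts[key] += 1
            for k1, k2 in itertools.combinations(items, 2):
                pair_counts[(k1, k2)] = pair_counts.get((k1, k2), 0) + 1
            rows.append(_dummy_row(profile, space))
    X = np.asarray(rows, dtype=float)
    missing = [
        (a.name, lv)
        for a in space.attributes
        for lv in a.levels
        if lv != a.reference and level_counts[(a.name, lv)] == 0
    ]
    full_rank = np.linalg.matrix_rank(X) == X.shape[1]
    return CoverageReport(
        level_counts=level_counts,
        pair_counts=pair_counts,
        estimable=(not missing) and full_rank,
        missing_levels=missing,
    )


def _dummy_row(profile: Profile, space: AttributeSpace) -> list[int]:
    row = []
    d = profile.as_dict
    for a in space.attributes:
        for lv in a.levels:
            if lv != a.reference:
                row.append(1 if d[a.name] == lv else 0)
    return row


def johnson_orme_min_n(c: int, t: int, a: int) -> int:
    """Johnson–Orme rule-of-thumb minimum sample size, ceil(500 c / (t a)).

    ``c`` is the largest number of levels of any attribute, ``t`` the number
    of alternatives per choice set (excluding the opt-out), and ``a`` the
    number of choice sets per respondent.  The rule is a strict lower bound:
    a sample of exactly this size sits on the boundary and more respondents
    are preferable.
    """
    if c <= 0 or t <= 0 or a <= 0:
        raise ValueError("c, t and a must be positive integers")
    return math.ceil(500 * c / (t * a))
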