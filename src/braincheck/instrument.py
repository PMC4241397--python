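"""BrainCheck instrument: items, scores and case-finding decisions.

BrainCheck is a very brief dementia case-finding tool for primary care.
It combines three sources of information:

* five yes/no patient questions — Q1–Q3 ask about subjective memory
  decline, Q4–Q5 about depressed mood and loss of interest;
* five yes/no clock-drawing criteria — CDT-1–CDT-4 score specific
  features of the drawn clock, CDT-5 is the examiner's global judgment
  "was the clock, including the written time, perfect?";
* the short seven-item informant questionnaire (IQCODE), each item
  rated 1 ("much improved") to 5 ("much worse") relative to two years
  earlier, summarised as the mean rating.  Up to two missing items are
  tolerated, in which case the mean of the remaining items is used.

Two decision paths are provided.  The *patient-only* path walks a
binary decision tree over the yes/no items and is meant for the
situation in which no informant is available.  The *combined* path
(BrainCheck proper) first applies a safety-net referral rule — the
patient-directed result is abnormal AND the informant mean is at or
above the referral threshold — and then dispatches on the
(Q1, Q2, Q3, CDT-5) subgroup to a subgroup-specific IQCODE cutoff or an
unconditional decision.  All cutoff comparisons use the at-or-above
convention: a mean equal to the cutoff indicates further evaluation.

The outcome is always one of two recommendations: ``further_evaluation``
(start a diagnostic work-up) or ``watchful_waiting`` (re-screen in 6 to
12 months).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

__all__ = [
    "PATIENT_ITEMS",
    "QUESTION_ITEMS",
    "CDT_ITEMS",
    "N_IQCODE_ITEMS",
    "MAX_IQCODE_MISSING",
    "InputError",
    "InvalidScoreError",
    "Decision",
    "PatientResponses",
    "IqcodeResponses",
    "IqcodeScore",
    "Leaf",
    "Split",
    "DecisionTree",
    "SubgroupRule",
    "RuleSet",
    "score_iqcode",
    "patient_only_decision",
    "combined_decision",
    "subgroup_of",
    "first_referred_mean",
    "default_tree",
    "default_rule_set",
    "DEFAULT_REFERRAL_THRESHOLD",
    "DEFAULT_SUBGROUP_CUTOFFS",
]

#: Canonical item order of the patient-directed instrument.
PATIENT_ITEMS: tuple[str, ...] = (
    "q1", "q2", "q3", "q4", "q5",
    "cdt1", "cdt2", "cdt3", "cdt4", "cdt5",
)
QUESTION_ITEMS: tuple[str, ...] = PATIENT_ITEMS[:5]
CDT_ITEMS: tuple[str, ...] = PATIENT_ITEMS[5:]

N_IQCODE_ITEMS = 7
#: Informant questionnaires with more missing items than this are invalid.
MAX_IQCODE_MISSING = 2

#: Referral threshold of the combined algorithm's safety-net rule
#: (patient-directed result abnormal AND informant mean at/above this).
DEFAULT_REFERRAL_THRESHOLD = 3.29

#: Published subgroup-specific IQCODE cutoffs of the combined algorithm.
DEFAULT_SUBGROUP_CUTOFFS: dict[str, float] = {
    "Q1=no & Q2=yes": 3.07,
    "Q1=no & Q2=no": 3.50,
    "Q1=yes & Q2=no & Q3=no & CDT5=yes": 3.31,
}


class InputError(ValueError):
    """A malformed or incomplete instrument input."""


class InvalidScoreError(InputError):
    """An operation was given an IQCODE score that is not valid."""


class Decision(str, Enum):
    """Case-finding outcome."""

    WATCHFUL_WAITING = "watchful_waiting"
    FURTHER_EVALUATION = "further_evaluation"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _check_binary(name: str, value: object) -> bool:
    if not isinstance(value, bool):
        raise InputError(
            f"item {name!r} must be a yes/no answer (bool), got {value!r}"
        )
    return value


@dataclass(frozen=True)
class PatientResponses:
    """The ten yes/no answers of the patient-directed instrument.

    ``True`` means "yes".  For Q1–Q5 a "yes" endorses the symptom; for
    the clock-drawing criteria a "yes" means the criterion was met
    (i.e. the clock feature was correct).  All ten answers are
    mandatory: the instrument has no missing-data convention on the
    patient side.
    """

    q1: bool
    q2: bool
    q3: bool
    q4: bool
    q5: bool
    cdt1: bool
    cdt2: bool
    cdt3: bool
    cdt4: bool
    cdt5: bool

    def __post_init__(self) -> None:
        for name in PATIENT_ITEMS:
            _check_binary(name, getattr(self, name))

    @classmethod
    def from_mapping(cls, values: Mapping[str, bool]) -> "PatientResponses":
        missing = [k for k in PATIENT_ITEMS if k not in values]
        if missing:
            raise InputError(f"missing patient items: {', '.join(missing)}")
        extra = set(values) - set(PATIENT_ITEMS)
        if extra:
            raise InputError(f"unknown patient items: {', '.join(sorted(extra))}")
        return cls(**{k: values[k] for k in PATIENT_ITEMS})

    def as_dict(self) -> dict[str, bool]:
        return {k: getattr(self, k) for k in PATIENT_ITEMS}


@dataclass(frozen=True)
class IqcodeResponses:
    """Seven ordinal informant ratings, each 1..5 or ``None`` (missing)."""

    items: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_IQCODE_ITEMS:
            raise InputError(
                f"IQCODE requires exactly {N_IQCODE_ITEMS} items, "
                f"got {len(self.items)}"
            )
        for i, v in enumerate(self.items, start=1):
            if v is None:
                continue
            if not isinstance(v, int) or isinstance(v, bool) or not 1 <= v <= 5:
                raise InputError(
                    f"IQCODE item {i} must be an integer 1..5 or missing, "
                    f"got {v!r}"
                )

    @property
    def n_missing(self) -> int:
        return sum(1 for v in self.items if v is None)


@dataclass(frozen=True)
class IqcodeScore:
    """Summary of an informant questionnaire.

    ``valid`` is ``True`` iff at most :data:`MAX_IQCODE_MISSING` items
    are missing; only then is ``mean`` defined (the arithmetic mean of
    the non-missing items, kept at full floating precision).
    """

    mean: Optional[float]
    n_missing: int
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and (self.mean is None or not 1.0 <= self.mean <= 5.0):
            raise InputError(f"valid IQCODE mean must lie in [1, 5], got {self.mean!r}")


def score_iqcode(responses: IqcodeResponses) -> IqcodeScore:
    """Score a seven-item informant questionnaire.

    The score is the mean of the non-missing ratings.  At most two
    missing answers are allowed; with three or more the questionnaire
    is flagged invalid and carries no mean.
    """
    present = [v for v in responses.items if v is not None]
    n_missing = responses.n_missing
    if n_missing > MAX_IQCODE_MISSING:
        return IqcodeScore(mean=None, n_missing=n_missing, valid=False)
    return IqcodeScore(
        mean=sum(present) / len(present), n_missing=n_missing, valid=True
    )


# ---------------------------------------------------------------------------
# Decision tree (patient-only algorithm)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Leaf:
    decision: Decision


@dataclass(frozen=True)
class Split:
    """Internal node asking one yes/no item; ``yes``/``no`` are subtrees."""

    item: str
    yes: "Node"
    no: "Node"


Node = Union[Leaf, Split]


@dataclass(frozen=True)
class DecisionTree:
    """Binary decision tree over the yes/no patient items.

    ``provenance`` tags where the topology came from: ``"reconstructed"``
    for the shipped default (the published figure's internal structure is
    only partially documented, see :func:`default_tree`) or ``"derived"``
    for trees fitted from data.
    """

    root: Node
    provenance: str = "derived"

    def __post_init__(self) -> None:
        self._validate(self.root, frozenset())

    def _validate(self, node: Node, seen: frozenset[str]) -> None:
        if isinstance(node, Leaf):
            if not isinstance(node.decision, Decision):
                raise InputError(f"leaf decision must be a Decision, got {node.decision!r}")
            return
        if node.item not in PATIENT_ITEMS:
            raise InputError(f"unknown tree item {node.item!r}")
        if node.item in seen:
            raise InputError(f"item {node.item!r} repeated along a root-to-leaf path")
        child_seen = seen | {node.item}
        self._validate(node.yes, child_seen)
        self._validate(node.no, child_seen)

    def decide(self, values: Mapping[str, bool]) -> Decision:
        node = self.root
        while isinstance(node, Split):
            if node.item not in values or values[node.item] is None:
                raise InputError(f"missing answer for consulted item {node.item!r}")
            node = node.yes if _check_binary(node.item, values[node.item]) else node.no
        return node.decision

    def items_used(self) -> tuple[str, ...]:
        """Items consulted anywhere in the tree, in canonical item order."""
        used: set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, Split):
                used.add(node.item)
                walk(node.yes)
                walk(node.no)

        walk(self.root)
        return tuple(i for i in PATIENT_ITEMS if i in used)

    def n_leaves(self) -> int:
        def count(node: Node) -> int:
            if isinstance(node, Leaf):
                return 1
            return count(node.yes) + count(node.no)

        return count(self.root)


def patient_only_decision(
    responses: Union[PatientResponses, Mapping[str, bool]],
    tree: DecisionTree,
) -> Decision:
    """Classify a patient from the patient-directed items alone.

    Deterministic: the same responses and tree always yield the same
    decision.  A missing consulted item raises :class:`InputError`
    naming the item.
    """
    values = responses.as_dict() if isinstance(responses, PatientResponses) else responses
    return tree.decide(values)


def default_tree() -> DecisionTree:
    """The shipped patient-only decision tree.

    The published description fixes the root (CDT-5, the global
    "perfect clock" judgment), the middle level (Q1–Q3 and CDT-3) and
    the excluded items (Q4 and Q5 were dropped from the final
    algorithm), but not the full leaf mapping.  This reconstruction is
    consistent with those constraints and is tagged
    ``provenance="reconstructed"``; the derivation module can refit a
    tree from data instead.
    """
    fe = Leaf(Decision.FURTHER_EVALUATION)
    ww = Leaf(Decision.WATCHFUL_WAITING)
    perfect_clock = Split(
        "q1",
        yes=Split("q2", yes=fe, no=Split("q3", yes=fe, no=ww)),
        no=ww,
    )
    imperfect_clock = Split(
        "cdt3",
        yes=Split("q1", yes=fe, no=Split("q2", yes=fe, no=ww)),
        no=fe,
    )
    return DecisionTree(
        root=Split("cdt5", yes=perfect_clock, no=imperfect_clock),
        provenance="reconstructed",
    )


# ---------------------------------------------------------------------------
# Combined (patient + informant) rule set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupRule:
    """One branch of the combined algorithm.

    ``cells`` enumerates the item-value combinations (tuples aligned
    with the rule set's ``items``) the rule covers.  Exactly one of
    ``cutoff`` (refer when the IQCODE mean is at or above it) and
    ``decision`` (unconditional outcome) is set.
    """

    cells: frozenset[tuple[bool, ...]]
    cutoff: Optional[float] = None
    decision: Optional[Decision] = None
    description: str = ""

    def __post_init__(self) -> None:
        if (self.cutoff is None) == (self.decision is None):
            raise InputError(
                "a subgroup rule carries either a cutoff or an unconditional "
                "decision, not both/neither"
            )
        if self.cutoff is not None and not 1.0 <= self.cutoff <= 5.0:
            raise InputError(f"IQCODE cutoff must lie in [1, 5], got {self.cutoff!r}")
        if not self.cells:
            raise InputError("a subgroup rule must cover at least one cell")

    def matches(self, values: tuple[bool, ...]) -> bool:
        return values in self.cells


@dataclass(frozen=True)
class RuleSet:
    """The combined BrainCheck decision algorithm.

    Evaluation order follows the published list: first the safety-net
    referral rule (``patient_result`` abnormal AND informant mean at or
    above ``referral_threshold``), then the unique subgroup rule
    matching the values of ``items``.  Subgroup rules must partition
    the full value space of ``items`` (mutually exclusive, jointly
    exhaustive).
    """

    items: tuple[str, ...]
    referral_threshold: float
    rules: tuple[SubgroupRule, ...]
    provenance: str = "reference-instrument"

    def __post_init__(self) -> None:
        if not self.items:
            raise InputError("rule set must dispatch on at least one item")
        for item in self.items:
            if item not in PATIENT_ITEMS:
                raise InputError(f"unknown rule-set item {item!r}")
        if not 1.0 <= self.referral_threshold <= 5.0:
            raise InputError(
                f"referral threshold must lie in [1, 5], got {self.referral_threshold!r}"
            )
        space = list(itertools.product([False, True], repeat=len(self.items)))
        for combo in space:
            n = sum(1 for r in self.rules if r.matches(combo))
            if n != 1:
                pretty = ", ".join(
                    f"{it}={'yes' if v else 'no'}" for it, v in zip(self.items, combo)
                )
                raise InputError(
                    f"subgroup rules must match every combination exactly once; "
                    f"({pretty}) matched {n} rules"
                )

    def subgroup_for(self, values: Mapping[str, bool]) -> SubgroupRule:
        """The unique subgroup rule matching ``values`` (keyed by item name)."""
        try:
            combo = tuple(_check_binary(i, values[i]) for i in self.items)
        except KeyError as e:
            raise InputError(f"missing answer for rule-set item {e.args[0]!r}") from None
        for rule in self.rules:
            if rule.matches(combo):
                return rule
        raise AssertionError(
            "internal consistency error: no subgroup matched a validated rule set"
        )  # pragma: no cover - partition checked at construction

    def decide(
        self,
        values: Mapping[str, bool],
        patient_result: Decision,
        iqcode: IqcodeScore,
    ) -> Decision:
        if not iqcode.valid:
            raise InvalidScoreError(
                "IQCODE score is invalid (more than "
                f"{MAX_IQCODE_MISSING} missing items); use patient_only_decision "
                "for this case instead"
            )
        return self._decide_mean(values, patient_result, iqcode.mean)

    def _decide_mean(
        self,
        values: Mapping[str, bool],
        patient_result: Decision,
        mean: float,
    ) -> Decision:
        # Rule 1 (safety net): abnormal patient-directed result AND
        # informant mean at/above the referral threshold.
        if (
            patient_result is Decision.FURTHER_EVALUATION
            and mean >= self.referral_threshold
        ):
            return Decision.FURTHER_EVALUATION
        rule = self.subgroup_for(values)
        if rule.decision is not None:
            return rule.decision
        if mean >= rule.cutoff:
            return Decision.FURTHER_EVALUATION
        return Decision.WATCHFUL_WAITING


def default_rule_set() -> RuleSet:
    """The published combined decision rules, in printed order.

    1. patient-directed result abnormal & mean >= 3.29 -> refer;
    2. Q1=no & Q2=yes -> cutoff 3.07;
    3. Q1=no & Q2=no -> cutoff 3.50;
    4. Q1=yes & Q2=no & Q3=no & CDT-5=yes -> cutoff 3.31;
    5. Q1=yes & not(Q2=no & Q3=no & CDT-5=yes) -> refer unconditionally.
    """
    items = ("q1", "q2", "q3", "cdt5")
    space = list(itertools.product([False, True], repeat=4))

    def cells(pred) -> frozenset[tuple[bool, ...]]:
        return frozenset(c for c in space if pred(dict(zip(items, c))))

    rules = (
        SubgroupRule(
            cells=cells(lambda v: not v["q1"] and v["q2"]),
            cutoff=3.07,
            description="Q1=no & Q2=yes",
        ),
        SubgroupRule(
            cells=cells(lambda v: not v["q1"] and not v["q2"]),
            cutoff=3.50,
            description="Q1=no & Q2=no",
        ),
        SubgroupRule(
            cells=cells(
                lambda v: v["q1"] and not v["q2"] and not v["q3"] and v["cdt5"]
            ),
            cutoff=3.31,
            description="Q1=yes & Q2=no & Q3=no & CDT5=yes",
        ),
        SubgroupRule(
            cells=cells(
                lambda v: v["q1"]
                and not (not v["q2"] and not v["q3"] and v["cdt5"])
            ),
            decision=Decision.FURTHER_EVALUATION,
            description="Q1=yes & not(Q2=no & Q3=no & CDT5=yes)",
        ),
    )
    return RuleSet(
        items=items,
        referral_threshold=DEFAULT_REFERRAL_THRESHOLD,
        rules=rules,
        provenance="reference-instrument",
    )


def combined_decision(
    q1: bool,
    q2: bool,
    q3: bool,
    cdt5: bool,
    patient_result: Decision,
    iqcode: IqcodeScore,
    rules: Optional[RuleSet] = None,
) -> Decision:
    """Apply the combined (BrainCheck) decision algorithm to one case.

    Requires a valid informant score; otherwise raises
    :class:`InvalidScoreError` with the instruction to fall back to
    :func:`patient_only_decision`.
    """
    rules = rules if rules is not None else default_rule_set()
    values = {"q1": q1, "q2": q2, "q3": q3, "cdt5": cdt5}
    extra = set(rules.items) - set(values)
    if extra:
        raise InputError(
            f"rule set dispatches on items outside (q1,q2,q3,cdt5): {sorted(extra)}; "
            "use RuleSet.decide with a full item mapping"
        )
    return rules.decide(values, patient_result, iqcode)


def subgroup_of(
    q1: bool,
    q2: bool,
    q3: bool,
    cdt5: bool,
    rules: Optional[RuleSet] = None,
) -> SubgroupRule:
    """The unique subgroup rule a (Q1, Q2, Q3, CDT-5) combination falls in."""
    rules = rules if rules is not None else default_rule_set()
    return rules.subgroup_for({"q1": q1, "q2": q2, "q3": q3, "cdt5": cdt5})


def first_referred_mean(
    rules: RuleSet,
    values: Mapping[str, bool],
    patient_result: Decision,
    lo: float = 1.0,
    hi: float = 5.0,
    step: float = 0.01,
) -> Optional[float]:
    """Smallest IQCODE mean (ascending grid search) that triggers referral.

    Sweeps means from ``lo`` to ``hi`` in ``step`` increments (grid
    points are computed as exact integer ratios to avoid accumulated
    float error) and returns the first mean for which the combined
    algorithm indicates further evaluation, or ``None`` if none does.
    """
    denom = round(1.0 / step)
    for i in range(round(lo * denom), round(hi * denom) + 1):
        mean = i / denom
        score = IqcodeScore(mean=mean, n_missing=0, valid=True)
        if rules.decide(values, patient_result, score) is Decision.FURTHER_EVALUATION:
            return mean
    return None
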