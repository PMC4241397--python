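"""Statistical derivation pipeline for the combined decision algorithm.

This module re-implements the pipeline that produced the BrainCheck
rules from a labeled cohort (memory-clinic diagnosis as gold standard):

1. CART recursive partitioning over the ten yes/no patient items
   selects the discriminating items (:func:`fit_cart`), with bootstrap
   stability of the selection (:func:`bootstrap_tree_stability`);
2. a contingency table of the selected items against the group
   variable (:func:`build_contingency`), from which items that do not
   affect the categorization are pruned
   (:func:`prune_noninformative`);
3. homogeneous subgroups — cells with a distinctly high or low
   proportion of patients, merged with like neighbours — form a
   preliminary classification (:func:`find_homogeneous_subgroups`);
4. a subgroup-specific IQCODE cutoff is optimized per subgroup by ROC
   analysis maximizing the correct classification rate
   (:func:`roc_optimal_cutoff`);
5. the assembled rule set (:func:`derive_combined_rules`) is evaluated
   in bootstrap replicates (:func:`bootstrap_evaluate`).

The CART here follows rpart's conventions: Gini impurity by default
and a complexity-parameter stop — a split is kept only when its
impurity decrease exceeds ``cp`` times the root node risk.  Ties
between equally good splits go to the earlier item in the supplied
item order, so fits are exactly reproducible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .instrument import (
    PATIENT_ITEMS,
    Decision,
    DecisionTree,
    InputError,
    IqcodeResponses,
    IqcodeScore,
    Leaf,
    PatientResponses,
    RuleSet,
    Split,
    SubgroupRule,
    patient_only_decision,
    score_iqcode,
)
from .metrics import CONTROL, PATIENT, classification_metrics

__all__ = [
    "CohortRecord",
    "CartParams",
    "ContingencyTable",
    "SubgroupDefinition",
    "RocResult",
    "BootstrapSummary",
    "DerivationReport",
    "DerivationError",
    "DerivationWarning",
    "homogeneity_class",
    "fit_cart",
    "bootstrap_tree_stability",
    "build_contingency",
    "prune_noninformative",
    "find_homogeneous_subgroups",
    "roc_optimal_cutoff",
    "derive_combined_rules",
    "run_derivation",
    "bootstrap_evaluate",
]


class DerivationError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class DerivationWarning(UserWarning):
    """Non-fatal pipeline condition (fallbacks, exclusions, degeneracies)."""


def _warn(collected: Optional[list], message: str) -> None:
    warnings.warn(message, DerivationWarning, stacklevel=3)
    if collected is not None:
        collected.append(message)


@dataclass(frozen=True)
class CohortRecord:
    """One case for scoring, derivation or evaluation.

    ``label`` is the gold-standard group (``control``/``patient``) or
    ``None`` for scoring-only cohorts without a reference diagnosis;
    every derivation and evaluation operation requires labels.
    """

    patient: PatientResponses
    label: Optional[str]
    iqcode: Optional[IqcodeResponses] = None
    diagnosis: Optional[str] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (CONTROL, PATIENT):
            raise InputError(
                f"label must be 'control' or 'patient', got {self.label!r}"
            )

    def iqcode_score(self) -> Optional[IqcodeScore]:
        return None if self.iqcode is None else score_iqcode(self.iqcode)


def _require_labels(cohort: Sequence[CohortRecord], op: str) -> None:
    n = sum(1 for r in cohort if r.label is None)
    if n:
        raise InputError(f"{op} requires gold-standard labels; {n} record(s) unlabeled")


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CartParams:
    """Tuning of the recursive-partitioning fit.

    ``complexity_parameter`` (cp) is the minimum relative improvement —
    impurity decrease over root-node risk — a split must exceed to be
    kept (default 0.01, i.e. 1%).  ``min_node_size`` is the smallest
    node considered for splitting (default 20, rpart's ``minsplit``
    convention; lower it for toy cohorts).  ``impurity`` is ``"gini"``
    or ``"entropy"``.
    """

    complexity_parameter: float = 0.01
    min_node_size: int = 20
    impurity: str = "gini"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.complexity_parameter > 0:
            raise InputError("complexity_parameter must be > 0")
        if self.min_node_size < 1:
            raise InputError("min_node_size must be >= 1")
        if self.impurity not in ("gini", "entropy"):
            raise InputError(f"unknown impurity measure {self.impurity!r}")

    def to_dict(self) -> dict:
        return {
            "complexity_parameter": self.complexity_parameter,
            "min_node_size": self.min_node_size,
            "impurity": self.impurity,
            "seed": self.seed,
        }


def _impurity(n_control: float, n_patient: float, measure: str) -> float:
    n = n_control + n_patient
    if n == 0:
        return 0.0
    p = n_patient / n
    if measure == "gini":
        return 2.0 * p * (1.0 - p)
    out = 0.0
    for q in (p, 1.0 - p):
        if q > 0:
            out -= q * np.log2(q)
    return out


def _leaf_for(n_control: int, n_patient: int) -> Leaf:
    # Majority class; ties go to referral, the sensitive choice.
    if n_patient >= n_control:
        return Leaf(Decision.FURTHER_EVALUATION)
    return Leaf(Decision.WATCHFUL_WAITING)


def fit_cart(
    cohort: Sequence[CohortRecord],
    items: Sequence[str] = PATIENT_ITEMS,
    params: Optional[CartParams] = None,
) -> DecisionTree:
    """Fit a binary classification tree over yes/no items.

    Each split maximizes the impurity decrease among the items not yet
    used on the path; growth stops when the best decrease does not
    exceed ``cp`` times the root risk, when a node is smaller than
    ``min_node_size``, or when no item still varies.  Leaves carry the
    majority class (ties referred).  A single-class cohort yields a
    root-only tree with a warning.
    """
    params = params if params is not None else CartParams()
    items = tuple(items)
    if not items:
        raise InputError("fit_cart requires a non-empty item set")
    unknown = [i for i in items if i not in PATIENT_ITEMS]
    if unknown:
        raise InputError(f"unknown items: {unknown}")
    if not cohort:
        raise InputError("fit_cart requires a non-empty cohort")
    _require_labels(cohort, "fit_cart")

    X = np.array(
        [[getattr(r.patient, i) for i in items] for r in cohort], dtype=bool
    )
    y = np.array([r.label == PATIENT for r in cohort], dtype=bool)

    n = len(y)
    root_risk = n * _impurity(n - y.sum(), y.sum(), params.impurity)
    if root_risk == 0.0:
        warnings.warn(
            "single-class cohort: returning a root-only tree",
            DerivationWarning,
            stacklevel=2,
        )
        return DecisionTree(
            root=_leaf_for(int(n - y.sum()), int(y.sum())), provenance="derived"
        )

    min_gain = params.complexity_parameter * root_risk

    def grow(idx: np.ndarray, used: frozenset[str]):
        n_pat = int(y[idx].sum())
        n_ctl = int(idx.size - n_pat)
        node_imp = _impurity(n_ctl, n_pat, params.impurity)
        if (
            node_imp == 0.0
            or idx.size < params.min_node_size
            or len(used) == len(items)
        ):
            return _leaf_for(n_ctl, n_pat)
        node_risk = idx.size * node_imp
        best_gain, best_j = 0.0, None
        for j, item in enumerate(items):
            if item in used:
                continue
            yes = X[idx, j]
            n_yes = int(yes.sum())
            n_no = idx.size - n_yes
            if n_yes == 0 or n_no == 0:
                continue
            pat_yes = int(y[idx[yes]].sum())
            pat_no = n_pat - pat_yes
            child_risk = n_yes * _impurity(
                n_yes - pat_yes, pat_yes, params.impurity
            ) + n_no * _impurity(n_no - pat_no, pat_no, params.impurity)
            gain = node_risk - child_risk
            if gain > best_gain + 1e-12:  # ties keep the earlier item
                best_gain, best_j = gain, j
        # Strict inequality: a split must beat cp * root risk, so cp >= 1
        # (the whole root risk) can never be met and yields a stump.
        if best_j is None or not best_gain > min_gain:
            return _leaf_for(n_ctl, n_pat)
        yes_mask = X[idx, best_j]
        child_used = used | {items[best_j]}
        return Split(
            item=items[best_j],
            yes=grow(idx[yes_mask], child_used),
            no=grow(idx[~yes_mask], child_used),
        )

    return DecisionTree(root=grow(np.arange(n), frozenset()), provenance="derived")


def bootstrap_tree_stability(
    cohort: Sequence[CohortRecord],
    items: Sequence[str] = PATIENT_ITEMS,
    params: Optional[CartParams] = None,
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> dict[str, float]:
    """Per-item selection frequency across case-resampled CART refits."""
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    items = tuple(items)
    rng = np.random.default_rng(seed)
    counts = {i: 0 for i in items}
    n = len(cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DerivationWarning)
        for _ in range(n_reps):
            idx = rng.integers(0, n, n)
            tree = fit_cart([cohort[k] for k in idx], items, params)
            for item in tree.items_used():
                counts[item] += 1
    return {i: counts[i] / n_reps for i in items}


# ---------------------------------------------------------------------------
# Contingency table and homogeneous subgroups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """Counts of controls and patients per value-combination of items.

    ``cells`` maps each *observed* combination (tuple aligned with
    ``items``) to ``(n_control, n_patient)``.
    """

    items: tuple[str, ...]
    cells: Mapping[tuple[bool, ...], tuple[int, int]]

    @property
    def n(self) -> int:
        return sum(c + p for c, p in self.cells.values())

    def proportion(self, combo: tuple[bool, ...]) -> float:
        c, p = self.cells[combo]
        return p / (c + p)

    def marginalize(self, item: str) -> "ContingencyTable":
        """Collapse the table over one item."""
        j = self.items.index(item)
        merged: dict[tuple[bool, ...], list[int]] = {}
        for combo, (c, p) in self.cells.items():
            key = combo[:j] + combo[j + 1 :]
            acc = merged.setdefault(key, [0, 0])
            acc[0] += c
            acc[1] += p
        return ContingencyTable(
            items=self.items[:j] + self.items[j + 1 :],
            cells={k: (v[0], v[1]) for k, v in merged.items()},
        )

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "cells": [
                {
                    "values": ["yes" if v else "no" for v in combo],
                    "n_control": c,
                    "n_patient": p,
                    "patient_proportion": p / (c + p),
                }
                for combo, (c, p) in sorted(self.cells.items())
            ],
            "n": self.n,
        }


def build_contingency(
    cohort: Sequence[CohortRecord], items: Sequence[str]
) -> ContingencyTable:
    """Cross-tabulate item value-combinations against the group label."""
    items = tuple(items)
    if not cohort:
        raise InputError("build_contingency requires a non-empty cohort")
    if not items:
        raise InputError("build_contingency requires at least one item")
    _require_labels(cohort, "build_contingency")
    cells: dict[tuple[bool, ...], list[int]] = {}
    for r in cohort:
        combo = tuple(bool(getattr(r.patient, i)) for i in items)
        acc = cells.setdefault(combo, [0, 0])
        acc[1 if r.label == PATIENT else 0] += 1
    return ContingencyTable(items=items, cells={k: (v[0], v[1]) for k, v in cells.items()})


def homogeneity_class(p: float, high_threshold: float = 0.8, low_threshold: float = 0.2) -> str:
    """Classify a cell's patient proportion as ``high``, ``low`` or ``mixed``."""
    if not 0.0 <= low_threshold < high_threshold <= 1.0:
        raise InputError(
            "homogeneity thresholds must satisfy 0 <= low < high <= 1, got "
            f"low={low_threshold}, high={high_threshold}"
        )
    if p >= high_threshold:
        return "high"
    if p <= low_threshold:
        return "low"
    return "mixed"


def prune_noninformative(
    table: ContingencyTable,
    items: Optional[Sequence[str]] = None,
    high_threshold: float = 0.8,
    low_threshold: float = 0.2,
    tolerance: float = 0.0,
) -> tuple[str, ...]:
    """Drop items that do not change the homogeneity classification.

    An item is non-informative when, for every combination of the
    remaining items, its two value-strata carry the same homogeneity
    class (equivalently, proportions within ``tolerance``); a stratum
    that was never observed imposes no constraint.  Items are examined
    in order and the table re-collapsed after each drop, until stable.
    Returns the retained item subset.
    """
    candidates = tuple(items) if items is not None else table.items
    current = table

    def droppable(t: ContingencyTable, item: str) -> bool:
        j = t.items.index(item)
        strata: dict[tuple, dict[bool, float]] = {}
        for combo in t.cells:
            key = combo[:j] + combo[j + 1 :]
            strata.setdefault(key, {})[combo[j]] = t.proportion(combo)
        for pair in strata.values():
            if len(pair) < 2:
                continue
            p_yes, p_no = pair[True], pair[False]
            same_class = homogeneity_class(
                p_yes, high_threshold, low_threshold
            ) == homogeneity_class(p_no, high_threshold, low_threshold)
            if not (same_class or abs(p_yes - p_no) <= tolerance):
                return False
        return True

    changed = True
    while changed and len(current.items) > 1:
        changed = False
        for item in current.items:
            if item in candidates and droppable(current, item):
                current = current.marginalize(item)
                changed = True
                break
    return current.items


@dataclass(frozen=True)
class SubgroupDefinition:
    """A maximal union of like-classified contingency cells."""

    items: tuple[str, ...]
    cells: frozenset[tuple[bool, ...]]
    patient_proportion: float
    homogeneity: str

    def contains(self, record: CohortRecord) -> bool:
        return tuple(bool(getattr(record.patient, i)) for i in self.items) in self.cells

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "cells": [["yes" if v else "no" for v in c] for c in sorted(self.cells)],
            "patient_proportion": self.patient_proportion,
            "homogeneity": self.homogeneity,
        }


def find_homogeneous_subgroups(
    table: ContingencyTable,
    high_threshold: float = 0.8,
    low_threshold: float = 0.2,
) -> list[SubgroupDefinition]:
    """Partition observed cells into homogeneity subgroups.

    Each observed cell is classified high/low/mixed by its patient
    proportion; cells differing in a single item value ("adjacent") and
    sharing a class are merged transitively into one subgroup.  The
    pooled patient proportion of each subgroup is reported.
    """
    if not 0.0 <= low_threshold < high_threshold <= 1.0:
        raise InputError(
            "homogeneity thresholds must satisfy 0 <= low < high <= 1, got "
            f"low={low_threshold}, high={high_threshold}"
        )
    combos = sorted(table.cells)
    cls = {
        c: homogeneity_class(table.proportion(c), high_threshold, low_threshold)
        for c in combos
    }
    parent = {c: c for c in combos}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a, b in itertools.combinations(combos, 2):
        if cls[a] == cls[b] and sum(x != y for x, y in zip(a, b)) == 1:
            parent[find(a)] = find(b)

    groups: dict[tuple, list] = {}
    for c in combos:
        groups.setdefault(find(c), []).append(c)

    subgroups = []
    for members in sorted(groups.values(), key=lambda m: min(m)):
        n_ctl = sum(table.cells[c][0] for c in members)
        n_pat = sum(table.cells[c][1] for c in members)
        subgroups.append(
            SubgroupDefinition(
                items=table.items,
                cells=frozenset(members),
                patient_proportion=n_pat / (n_ctl + n_pat),
                homogeneity=cls[members[0]],
            )
        )
    return subgroups


# ---------------------------------------------------------------------------
# ROC cutoff optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    """Optimal at-or-above cutoff with the performance it attains."""

    cutoff: float
    sensitivity: float
    specificity: float
    ccr: float
    candidates: tuple[float, ...]

    @property
    def cutoff_2dp(self) -> float:
        """Cutoff rounded to two decimals, the instrument's display precision."""
        return round(self.cutoff, 2)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "cutoff_2dp": self.cutoff_2dp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ccr": self.ccr,
            "n_candidates": len(self.candidates),
        }


def roc_optimal_cutoff(
    scores: Sequence[float],
    labels: Sequence[str],
    criterion: str = "maximize_ccr",
) -> RocResult:
    """Cutoff on a continuous score maximizing the CCR.

    Candidate cutoffs are the midpoints between consecutive distinct
    sorted scores plus the extremes: the minimum score (classify
    everyone positive under the at-or-above convention) and a value
    just above the maximum (classify no one positive).  Ties in CCR go
    to the lowest cutoff, i.e. the most sensitive choice.
    """
    if criterion != "maximize_ccr":
        raise InputError(f"unsupported criterion {criterion!r}")
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0 or scores.size != len(labels):
        raise InputError("scores and labels must be non-empty and of equal length")
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    y = np.array([l == PATIENT for l in labels], dtype=bool)
    n_pat = int(y.sum())
    n_ctl = int(y.size - n_pat)
    if n_pat == 0 or n_ctl == 0:
        raise InputError("both labels must be represented for ROC optimization")

    u = np.unique(scores)
    candidates = np.concatenate(
        [[u[0]], (u[:-1] + u[1:]) / 2.0, [np.nextafter(u[-1], np.inf)]]
    )
    best = None
    for c in candidates:
        pos = scores >= c
        tp = int((pos & y).sum())
        tn = int((~pos & ~y).sum())
        ccr = (tp + tn) / y.size
        if best is None or ccr > best[0] + 1e-12:
            best = (ccr, c, tp / n_pat, tn / n_ctl)
    ccr, cutoff, sens, spec = best
    return RocResult(
        cutoff=float(cutoff),
        sensitivity=sens,
        specificity=spec,
        ccr=ccr,
        candidates=tuple(float(c) for c in candidates),
    )


# ---------------------------------------------------------------------------
# Rule-set assembly
# ---------------------------------------------------------------------------

def _describe_cells(items: tuple[str, ...], cells: frozenset[tuple[bool, ...]]) -> str:
    """Human-readable predicate: fixed items as a conjunction, else cell count."""
    cells_list = sorted(cells)
    fixed = []
    for j, item in enumerate(items):
        values = {c[j] for c in cells_list}
        if len(values) == 1:
            v = values.pop()
            fixed.append(f"{item.upper()}={'yes' if v else 'no'}")
    conj = " & ".join(fixed) if fixed else "any"
    if 2 ** (len(items) - len(fixed)) != len(cells_list):
        conj += f" [{len(cells_list)} cells]"
    return conj


@dataclass
class DerivationReport:
    """All artifacts of one derivation run (serializable via ``to_dict``)."""

    tree: DecisionTree
    items_selected: tuple[str, ...]
    initial_table: ContingencyTable
    items_retained: tuple[str, ...]
    table: ContingencyTable
    subgroups: list[SubgroupDefinition]
    roc_results: dict[str, RocResult]
    referral_roc: Optional[RocResult]
    rules: RuleSet
    cart_params: CartParams
    high_threshold: float
    low_threshold: float
    n_records: int
    n_excluded_iqcode: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        from .io import tree_to_dict, ruleset_to_dict

        return {
            "tree": tree_to_dict(self.tree),
            "items_selected": list(self.items_selected),
            "initial_contingency": self.initial_table.to_dict(),
            "items_retained": list(self.items_retained),
            "contingency": self.table.to_dict(),
            "subgroups": [s.to_dict() for s in self.subgroups],
            "roc": {k: v.to_dict() for k, v in sorted(self.roc_results.items())},
            "referral_roc": None if self.referral_roc is None else self.referral_roc.to_dict(),
            "rules": ruleset_to_dict(self.rules),
            "cart_params": self.cart_params.to_dict(),
            "high_threshold": self.high_threshold,
            "low_threshold": self.low_threshold,
            "n_records": self.n_records,
            "n_excluded_iqcode": self.n_excluded_iqcode,
            "warnings": list(self.warnings),
        }


def run_derivation(
    cohort: Sequence[CohortRecord],
    cart_params: Optional[CartParams] = None,
    high_threshold: float = 0.8,
    low_threshold: float = 0.2,
    items: Sequence[str] = PATIENT_ITEMS,
) -> DerivationReport:
    """Execute the full derivation pipeline and keep every artifact.

    Records without a valid informant score are excluded with a
    warning (mirroring the instrument's missing-data policy).  Stage
    failures raise :class:`DerivationError` naming the stage.
    """
    cart_params = cart_params if cart_params is not None else CartParams()
    _require_labels(cohort, "run_derivation")
    collected: list[str] = []

    scored = [(r, r.iqcode_score()) for r in cohort]
    usable = [(r, s) for r, s in scored if s is not None and s.valid]
    n_excluded = len(cohort) - len(usable)
    if n_excluded:
        _warn(
            collected,
            f"excluded {n_excluded} record(s) without a valid IQCODE score "
            "(missing questionnaire or >2 missing items)",
        )
    if not usable:
        raise DerivationError("input: no records with a valid IQCODE score")
    records = [r for r, _ in usable]
    means = {id(r): s.mean for r, s in usable}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except DerivationError:
            raise
        except Exception as e:
            raise DerivationError(f"{name}: {e}") from e

    tree = stage("fit_cart", fit_cart, records, items, cart_params)
    selected = tree.items_used()
    if not selected:
        raise DerivationError(
            "fit_cart: the fitted tree selected no items (no discriminating "
            "signal at this complexity parameter)"
        )

    initial_table = stage("build_contingency", build_contingency, records, selected)
    retained = stage(
        "prune_noninformative",
        prune_noninformative,
        initial_table,
        high_threshold=high_threshold,
        low_threshold=low_threshold,
    )
    table = stage("build_contingency", build_contingency, records, retained)
    subgroups = stage(
        "find_homogeneous_subgroups",
        find_homogeneous_subgroups,
        table,
        high_threshold,
        low_threshold,
    )

    roc_results: dict[str, RocResult] = {}
    rules: list[SubgroupRule] = []
    for sg in subgroups:
        desc = _describe_cells(sg.items, sg.cells)
        if sg.homogeneity == "high":
            rules.append(
                SubgroupRule(
                    cells=sg.cells,
                    decision=Decision.FURTHER_EVALUATION,
                    description=desc,
                )
            )
            continue
        members = [r for r in records if sg.contains(r)]
        member_labels = {r.label for r in members}
        if len(member_labels) < 2:
            only = member_labels.pop()
            decision = (
                Decision.FURTHER_EVALUATION
                if only == PATIENT
                else Decision.WATCHFUL_WAITING
            )
            _warn(
                collected,
                f"subgroup ({desc}) contains a single class ({only}); assigned "
                f"the unconditional decision {decision.value}",
            )
            rules.append(SubgroupRule(cells=sg.cells, decision=decision, description=desc))
            continue
        roc = stage(
            f"roc_optimal_cutoff[{desc}]",
            roc_optimal_cutoff,
            [means[id(r)] for r in members],
            [r.label for r in members],
        )
        roc_results[desc] = roc
        if roc.cutoff > 5.0:
            _warn(
                collected,
                f"subgroup ({desc}): optimal cutoff refers no one; assigned "
                "unconditional watchful waiting",
            )
            rules.append(
                SubgroupRule(
                    cells=sg.cells,
                    decision=Decision.WATCHFUL_WAITING,
                    description=desc,
                )
            )
        else:
            rules.append(SubgroupRule(cells=sg.cells, cutoff=roc.cutoff, description=desc))

    observed = frozenset().union(*(sg.cells for sg in subgroups))
    complement = frozenset(
        c
        for c in itertools.product([False, True], repeat=len(retained))
        if c not in observed
    )
    if complement:
        _warn(
            collected,
            f"{len(complement)} item combination(s) unobserved in the cohort "
            "default to watchful waiting",
        )
        rules.append(
            SubgroupRule(
                cells=complement,
                decision=Decision.WATCHFUL_WAITING,
                description="unobserved combinations (default)",
            )
        )

    # Safety-net referral threshold: ROC over cases the patient-directed
    # tree already flags; falls back to the whole cohort when that subset
    # is single-class.
    abnormal = [
        r
        for r in records
        if patient_only_decision(r.patient, tree) is Decision.FURTHER_EVALUATION
    ]
    referral_roc = None
    pool = abnormal if len({r.label for r in abnormal}) == 2 else None
    if pool is None:
        _warn(
            collected,
            "patient-instrument-abnormal subset is single-class or empty; "
            "referral threshold optimized over the whole cohort instead",
        )
        pool = records
    try:
        referral_roc = roc_optimal_cutoff(
            [means[id(r)] for r in pool], [r.label for r in pool]
        )
        referral_threshold = min(referral_roc.cutoff, 5.0)
    except InputError as e:  # pragma: no cover - requires single-class cohort
        raise DerivationError(f"referral_threshold: {e}") from e

    rule_set = RuleSet(
        items=retained,
        referral_threshold=referral_threshold,
        rules=tuple(rules),
        provenance="derived",
    )
    return DerivationReport(
        tree=tree,
        items_selected=selected,
        initial_table=initial_table,
        items_retained=retained,
        table=table,
        subgroups=subgroups,
        roc_results=roc_results,
        referral_roc=referral_roc,
        rules=rule_set,
        cart_params=cart_params,
        high_threshold=high_threshold,
        low_threshold=low_threshold,
        n_records=len(records),
        n_excluded_iqcode=n_excluded,
        warnings=collected,
    )


def derive_combined_rules(
    cohort: Sequence[CohortRecord],
    cart_params: Optional[CartParams] = None,
    high_threshold: float = 0.8,
    low_threshold: float = 0.2,
) -> RuleSet:
    """Derive a combined rule set from a labeled cohort (see :func:`run_derivation`)."""
    return run_derivation(
        cohort, cart_params, high_threshold=high_threshold, low_threshold=low_threshold
    ).rules


# ---------------------------------------------------------------------------
# Bootstrap evaluation
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """Resampled operating characteristics of a fixed rule set.

    Per-replicate sensitivity/specificity/CCR (NaN where a replicate
    lacked the reference class), their means and 25th–75th percentile
    ("quartile") ranges over the defined replicates, and the count of
    excluded (undefined) replicates per statistic.
    """

    sensitivity: np.ndarray
    specificity: np.ndarray
    ccr: np.ndarray
    n_replicates: int
    seed: Optional[int]
    stratified: bool = False

    def _summary(self, values: np.ndarray) -> dict:
        defined = values[~np.isnan(values)]
        if defined.size == 0:
            return {"mean": None, "q25": None, "q75": None, "n_undefined": int(values.size)}
        return {
            "mean": float(defined.mean()),
            "q25": float(np.percentile(defined, 25)),
            "q75": float(np.percentile(defined, 75)),
            "n_undefined": int(values.size - defined.size),
        }

    @property
    def means(self) -> dict[str, Optional[float]]:
        return {
            name: self._summary(getattr(self, name))["mean"]
            for name in ("sensitivity", "specificity", "ccr")
        }

    def quartile_range(self, name: str) -> tuple[float, float]:
        s = self._summary(getattr(self, name))
        return (s["q25"], s["q75"])

    def format_line(self, name: str) -> str:
        """E.g. ``mean sensitivity of 97.4% (quartile range: 96.4 to 98.3%)``."""
        s = self._summary(getattr(self, name))
        return (
            f"mean {name} of {100 * s['mean']:.1f}% "
            f"(quartile range: {100 * s['q25']:.1f} to {100 * s['q75']:.1f}%)"
        )

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "stratified": self.stratified,
            **{
                name: self._summary(getattr(self, name))
                for name in ("sensitivity", "specificity", "ccr")
            },
        }


def bootstrap_evaluate(
    rules: RuleSet,
    tree: DecisionTree,
    cohort: Sequence[CohortRecord],
    n_reps: int = 10000,
    seed: Optional[int] = None,
    stratified: bool = False,
) -> BootstrapSummary:
    """Bootstrap the operating characteristics of fixed decision rules.

    Cases are resampled with replacement (non-stratified by default; the
    stratified option preserves the control/patient counts) and the
    *fixed* rules — no refitting — are scored on each replicate.  A
    replicate lacking one class leaves the corresponding rate undefined
    for that replicate; such replicates are excluded from that
    statistic's summary and counted.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    if not cohort:
        raise InputError("bootstrap_evaluate requires a non-empty cohort")
    _require_labels(cohort, "bootstrap_evaluate")

    is_patient = np.empty(len(cohort), dtype=bool)
    referred = np.empty(len(cohort), dtype=bool)
    for k, r in enumerate(cohort):
        s = r.iqcode_score()
        if s is None or not s.valid:
            raise InputError(
                f"record {r.id!r} lacks a valid IQCODE score; filter the cohort "
                "before evaluation"
            )
        pr = patient_only_decision(r.patient, tree)
        decision = rules.decide(r.patient.as_dict(), pr, s)
        is_patient[k] = r.label == PATIENT
        referred[k] = decision is Decision.FURTHER_EVALUATION

    rng = np.random.default_rng(seed)
    n = len(cohort)
    pat_idx = np.flatnonzero(is_patient)
    ctl_idx = np.flatnonzero(~is_patient)
    sens = np.empty(n_reps)
    spec = np.empty(n_reps)
    ccr = np.empty(n_reps)
    for b in range(n_reps):
        if stratified:
            idx = np.concatenate(
                [
                    rng.choice(pat_idx, pat_idx.size, replace=True),
                    rng.choice(ctl_idx, ctl_idx.size, replace=True),
                ]
            )
        else:
            idx = rng.integers(0, n, n)
        pat = is_patient[idx]
        pos = referred[idx]
        n_pat = int(pat.sum())
        n_ctl = n - n_pat
        sens[b] = (pos & pat).sum() / n_pat if n_pat else np.nan
        spec[b] = (~pos & ~pat).sum() / n_ctl if n_ctl else np.nan
        ccr[b] = ((pos & pat).sum() + (~pos & ~pat).sum()) / n
    return BootstrapSummary(
        sensitivity=sens,
        specificity=spec,
        ccr=ccr,
        n_replicates=n_reps,
        seed=seed,
        stratified=stratified,
    )


def evaluate_direct(
    rules: RuleSet, tree: DecisionTree, cohort: Sequence[CohortRecord]
):
    """Full-sample sensitivity/specificity/CCR of fixed rules (no resampling)."""
    _require_labels(cohort, "evaluate_direct")
    preds = []
    gold = []
    for r in cohort:
        s = r.iqcode_score()
        if s is None or not s.valid:
            raise InputError(
                f"record {r.id!r} lacks a valid IQCODE score; filter the cohort "
                "before evaluation"
            )
        pr = patient_only_decision(r.patient, tree)
        preds.append(rules.decide(r.patient.as_dict(), pr, s))
        gold.append(r.label)
    return classification_metrics(preds, gold)
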