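"""File formats: cohort CSV, rule-set / tree JSON, simulation params YAML.

Cohort CSV schema (UTF-8, header required, decimal point):

    id, q1..q5, cdt1..cdt5, iq1..iq7, group, diagnosis

``q*``/``cdt*`` take ``yes``/``no`` (case-insensitive); ``iq*`` take
``1``..``5`` or empty (missing); ``group`` is ``control``/``patient``;
``group``, ``diagnosis`` and the ``iq*`` block are optional columns.
Malformed rows are reported with their file line numbers.

Rule sets and trees serialize to versioned JSON documents with
provenance tags; thresholds are written as decimal strings whose
``float()`` round-trip is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .derivation import CohortRecord
from .instrument import (
    N_IQCODE_ITEMS,
    PATIENT_ITEMS,
    Decision,
    DecisionTree,
    InputError,
    IqcodeResponses,
    Leaf,
    PatientResponses,
    RuleSet,
    Split,
    SubgroupRule,
)
from .simulate import SimulationParams

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "tree_to_dict",
    "tree_from_dict",
    "write_tree_json",
    "read_tree_json",
    "ruleset_to_dict",
    "ruleset_from_dict",
    "write_ruleset_json",
    "read_ruleset_json",
    "read_simulation_params",
    "write_json",
]

SCHEMA_VERSION = "1"
_IQ_COLUMNS = tuple(f"iq{i}" for i in range(1, N_IQCODE_ITEMS + 1))
COHORT_COLUMNS = ("id", *PATIENT_ITEMS, *_IQ_COLUMNS, "group", "diagnosis")
_OPTIONAL_COLUMNS = {"group", "diagnosis", *_IQ_COLUMNS}


def _parse_yes_no(value: str, column: str, line: int) -> bool:
    v = value.strip().lower()
    if v == "yes":
        return True
    if v == "no":
        return False
    raise InputError(
        f"line {line}: column {column!r} must be yes/no, got {value!r}"
    )


def read_cohort_csv(path: Union[str, Path]) -> list[CohortRecord]:
    """Read and validate a cohort CSV; all row errors are reported at once."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise InputError(f"unknown column(s): {', '.join(unknown)}")
    required = [c for c in ("id", *PATIENT_ITEMS) if c not in df.columns]
    if required:
        raise InputError(f"missing required column(s): {', '.join(required)}")
    has_iq = any(c in df.columns for c in _IQ_COLUMNS)
    if has_iq:
        missing_iq = [c for c in _IQ_COLUMNS if c not in df.columns]
        if missing_iq:
            raise InputError(
                f"IQCODE columns must come as a complete block; missing: "
                f"{', '.join(missing_iq)}"
            )

    records: list[CohortRecord] = []
    errors: list[str] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        data = dict(zip(df.columns, row))
        try:
            patient_values = {
                item: _parse_yes_no(data[item], item, line) for item in PATIENT_ITEMS
            }
            iqcode = None
            if has_iq:
                items: list[Optional[int]] = []
                for c in _IQ_COLUMNS:
                    raw = data[c].strip()
                    if raw == "":
                        items.append(None)
                        continue
                    try:
                        items.append(int(raw))
                    except ValueError:
                        raise InputError(
                            f"line {line}: column {c!r} must be an integer 1..5 "
                            f"or empty, got {raw!r}"
                        ) from None
                try:
                    iqcode = IqcodeResponses(items=tuple(items))
                except InputError as e:
                    raise InputError(f"line {line}: {e}") from None
            label = data.get("group", "").strip().lower()
            if "group" in df.columns and label:
                if label not in ("control", "patient"):
                    raise InputError(
                        f"line {line}: column 'group' must be control/patient, "
                        f"got {data['group']!r}"
                    )
            else:
                label = None
            diagnosis = data.get("diagnosis", "").strip() or None
            records.append(
                CohortRecord(
                    patient=PatientResponses(**patient_values),
                    label=label,
                    iqcode=iqcode,
                    diagnosis=diagnosis,
                    id=data["id"].strip() or None,
                )
            )
        except InputError as e:
            errors.append(str(e))
    if errors:
        raise InputError("malformed cohort CSV:\n" + "\n".join(errors))
    return records


def write_cohort_csv(records: Sequence[CohortRecord], path: Union[str, Path]) -> None:
    rows = []
    any_iq = any(r.iqcode is not None for r in records)
    any_label = any(r.label in ("control", "patient") for r in records)
    for k, r in enumerate(records):
        row = {"id": r.id if r.id is not None else f"r{k + 1:04d}"}
        for item in PATIENT_ITEMS:
            row[item] = "yes" if getattr(r.patient, item) else "no"
        if any_iq:
            items = r.iqcode.items if r.iqcode is not None else (None,) * N_IQCODE_ITEMS
            for c, v in zip(_IQ_COLUMNS, items):
                row[c] = "" if v is None else str(v)
        if any_label:
            row["group"] = r.label if r.label is not None else ""
            if r.diagnosis:
                row["diagnosis"] = r.diagnosis
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df[[c for c in COHORT_COLUMNS if c in df.columns]]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Decision tree JSON
# ---------------------------------------------------------------------------

def _node_to_dict(node) -> dict:
    if isinstance(node, Leaf):
        return {"decision": node.decision.value}
    return {
        "item": node.item,
        "yes": _node_to_dict(node.yes),
        "no": _node_to_dict(node.no),
    }


def _node_from_dict(d: dict):
    if "decision" in d:
        return Leaf(Decision(d["decision"]))
    return Split(item=d["item"], yes=_node_from_dict(d["yes"]), no=_node_from_dict(d["no"]))


def tree_to_dict(tree: DecisionTree) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "decision_tree",
        "provenance": tree.provenance,
        "root": _node_to_dict(tree.root),
    }


def tree_from_dict(d: dict) -> DecisionTree:
    if d.get("kind") != "decision_tree":
        raise InputError("JSON document is not a decision tree")
    return DecisionTree(root=_node_from_dict(d["root"]), provenance=d.get("provenance", "derived"))


def write_tree_json(tree: DecisionTree, path: Union[str, Path]) -> None:
    write_json(tree_to_dict(tree), path)


def read_tree_json(path: Union[str, Path]) -> DecisionTree:
    with open(path, encoding="utf-8") as fh:
        return tree_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Rule-set JSON
# ---------------------------------------------------------------------------

def ruleset_to_dict(rules: RuleSet) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "rule_set",
        "provenance": rules.provenance,
        "items": list(rules.items),
        # decimal strings; repr(float) round-trips bit-exactly
        "referral_threshold": repr(rules.referral_threshold),
        "rules": [
            {
                "description": r.description,
                "cells": [["yes" if v else "no" for v in c] for c in sorted(r.cells)],
                "cutoff": None if r.cutoff is None else repr(r.cutoff),
                "decision": None if r.decision is None else r.decision.value,
            }
            for r in rules.rules
        ],
    }


def ruleset_from_dict(d: dict) -> RuleSet:
    if d.get("kind") != "rule_set":
        raise InputError("JSON document is not a rule set")
    rules = tuple(
        SubgroupRule(
            cells=frozenset(tuple(v == "yes" for v in cell) for cell in r["cells"]),
            cutoff=None if r["cutoff"] is None else float(r["cutoff"]),
            decision=None if r["decision"] is None else Decision(r["decision"]),
            description=r.get("description", ""),
        )
        for r in d["rules"]
    )
    return RuleSet(
        items=tuple(d["items"]),
        referral_threshold=float(d["referral_threshold"]),
        rules=rules,
        provenance=d.get("provenance", "derived"),
    )


def write_ruleset_json(rules: RuleSet, path: Union[str, Path]) -> None:
    write_json(ruleset_to_dict(rules), path)


def read_ruleset_json(path: Union[str, Path]) -> RuleSet:
    with open(path, encoding="utf-8") as fh:
        return ruleset_from_dict(json.load(fh))


def write_json(obj: dict, path: Union[str, Path]) -> None:
    """Deterministic JSON output (sorted keys, stable float repr)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Simulation parameter files (YAML or JSON)
# ---------------------------------------------------------------------------

def read_simulation_params(path: Union[str, Path]) -> SimulationParams:
    """Load :class:`SimulationParams` from a YAML (or JSON) mapping.

    Expected keys mirror the dataclass fields; ``endorsement`` and
    ``iqcode_dist`` are nested mappings keyed by group.
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InputError("simulation parameter file must contain a mapping")
    try:
        return SimulationParams(
            n_control=int(data["n_control"]),
            n_patient=int(data["n_patient"]),
            endorsement={
                g: {k: float(v) for k, v in items.items()}
                for g, items in data["endorsement"].items()
            },
            iqcode_dist={
                g: tuple(tuple(float(p) for p in dist) for dist in dists)
                for g, dists in data["iqcode_dist"].items()
            },
            missingness=tuple(
                float(m) for m in data.get("missingness", (0.0,) * N_IQCODE_ITEMS)
            ),
            latent_loading=float(data.get("latent_loading", 0.0)),
            seed=data.get("seed"),
        )
    except KeyError as e:
        raise InputError(f"simulation parameter file missing key {e.args[0]!r}") from None
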