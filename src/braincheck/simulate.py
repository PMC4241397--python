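"""Synthetic two-group cohorts with the structure the derivation assumes.

No clinical cohort is distributed with this package, so every pipeline
stage is exercised on simulated data: a control group and a patient
group with group-specific Bernoulli endorsement probabilities for the
ten yes/no patient items, group-specific ordinal distributions for the
seven informant items, and item-level missingness.  The default
parameters mimic the published validation cohort's *shape* (70
controls / 113 patients with informant data) with plausible — not
published — item distributions; see ``docs/methods.md`` for what these
simulations do and do not show about real data.

:func:`planted_cutoff_scenario` builds cohorts with known
subgroup-specific informant cutoffs so that the derivation pipeline's
parameter recovery can be checked against the generator as oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .derivation import CohortRecord
from .instrument import (
    N_IQCODE_ITEMS,
    PATIENT_ITEMS,
    InputError,
    IqcodeResponses,
    PatientResponses,
)
from .metrics import CONTROL, PATIENT

__all__ = [
    "SimulationParams",
    "PlantedSubgroup",
    "DEFAULT_PLANTED_SUBGROUPS",
    "default_simulation_params",
    "simulate_cohort",
    "planted_cutoff_scenario",
]

_GROUPS = (CONTROL, PATIENT)


@dataclass(frozen=True)
class SimulationParams:
    """Generating distributions of a simulated two-group cohort.

    ``endorsement[group][item]`` is the probability of answering "yes";
    ``iqcode_dist[group]`` holds seven probability vectors over the
    ratings 1..5; ``missingness`` is the per-item probability of a
    missing informant rating.  ``latent_loading`` in [0, 1) adds
    inter-item correlation to the informant ratings through a shared
    per-subject severity factor (Gaussian copula); 0 means independent
    items.
    """

    n_control: int
    n_patient: int
    endorsement: Mapping[str, Mapping[str, float]]
    iqcode_dist: Mapping[str, tuple[tuple[float, ...], ...]]
    missingness: tuple[float, ...] = (0.0,) * N_IQCODE_ITEMS
    latent_loading: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_patient < 0:
            raise InputError("group sizes must be non-negative")
        for g in _GROUPS:
            if g not in self.endorsement or g not in self.iqcode_dist:
                raise InputError(f"parameters for group {g!r} are required")
            for item in PATIENT_ITEMS:
                p = self.endorsement[g].get(item)
                if p is None or not 0.0 <= p <= 1.0:
                    raise InputError(
                        f"endorsement probability for {g}/{item} must be in [0, 1], got {p!r}"
                    )
            dists = self.iqcode_dist[g]
            if len(dists) != N_IQCODE_ITEMS:
                raise InputError(
                    f"{g}: expected {N_IQCODE_ITEMS} IQCODE item distributions"
                )
            for i, d in enumerate(dists, start=1):
                if len(d) != 5 or any(p < 0 for p in d):
                    raise InputError(f"{g}: IQCODE item {i} needs 5 non-negative probabilities")
                if abs(sum(d) - 1.0) > 1e-9:
                    raise InputError(
                        f"{g}: IQCODE item {i} distribution must sum to 1 "
                        f"(got {sum(d)!r})"
                    )
        if len(self.missingness) != N_IQCODE_ITEMS:
            raise InputError(f"missingness needs {N_IQCODE_ITEMS} per-item probabilities")
        for m in self.missingness:
            if not 0.0 <= m <= 1.0:
                raise InputError("missingness probabilities must be in [0, 1]")
        if not 0.0 <= self.latent_loading < 1.0:
            raise InputError("latent_loading must be in [0, 1)")


def default_simulation_params(
    n_control: int = 70,
    n_patient: int = 113,
    seed: Optional[int] = None,
) -> SimulationParams:
    """Plausible default cohort parameters.

    Group sizes default to the published informant subsample (70
    controls, 113 patients).  Symptom questions are endorsed more often
    by patients; clock criteria (a "yes" means the feature was correct)
    are met more often by controls — including the documented 68% of
    healthy participants who drew a perfect clock.  Informant ratings
    center on "no change" (3) for controls and shift toward "worse" for
    patients.  Item response distributions of the original cohort are
    unpublished; these values are placeholders with realistic
    qualitative structure.
    """
    endorsement = {
        CONTROL: {
            "q1": 0.25, "q2": 0.15, "q3": 0.10, "q4": 0.10, "q5": 0.10,
            "cdt1": 0.90, "cdt2": 0.85, "cdt3": 0.90, "cdt4": 0.85, "cdt5": 0.68,
        },
        PATIENT: {
            "q1": 0.75, "q2": 0.65, "q3": 0.55, "q4": 0.30, "q5": 0.30,
            "cdt1": 0.60, "cdt2": 0.55, "cdt3": 0.60, "cdt4": 0.50, "cdt5": 0.25,
        },
    }
    control_item = (0.02, 0.08, 0.70, 0.15, 0.05)
    patient_item = (0.01, 0.03, 0.25, 0.45, 0.26)
    return SimulationParams(
        n_control=n_control,
        n_patient=n_patient,
        endorsement=endorsement,
        iqcode_dist={
            CONTROL: (control_item,) * N_IQCODE_ITEMS,
            PATIENT: (patient_item,) * N_IQCODE_ITEMS,
        },
        missingness=(0.02,) * N_IQCODE_ITEMS,
        latent_loading=0.0,
        seed=seed,
    )


def _sample_iqcode(
    rng: np.random.Generator,
    dists: Sequence[Sequence[float]],
    missingness: Sequence[float],
    latent_loading: float,
) -> IqcodeResponses:
    from math import erf, sqrt

    items: list[Optional[int]] = []
    lam = latent_loading
    s = rng.standard_normal() if lam > 0 else 0.0
    for d, m in zip(dists, missingness):
        if m > 0 and rng.random() < m:
            items.append(None)
            continue
        if lam > 0:
            z = lam * s + np.sqrt(1.0 - lam * lam) * rng.standard_normal()
            u = 0.5 * (1.0 + erf(z / sqrt(2.0)))
        else:
            u = rng.random()
        cum = np.cumsum(d)
        items.append(int(np.searchsorted(cum, u, side="right")) + 1 if u < cum[-1] else 5)
    return IqcodeResponses(items=tuple(items))


def simulate_cohort(
    params: SimulationParams, seed: Optional[int] = None
) -> list[CohortRecord]:
    """Draw a labeled cohort from the configured distributions.

    Items are drawn independently per subject (and per item, unless a
    latent loading is configured).  ``seed`` overrides ``params.seed``;
    the same seed always reproduces the same cohort.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    records: list[CohortRecord] = []
    for group, n, prefix in (
        (CONTROL, params.n_control, "c"),
        (PATIENT, params.n_patient, "p"),
    ):
        probs = params.endorsement[group]
        dists = params.iqcode_dist[group]
        for k in range(n):
            responses = PatientResponses(
                **{item: bool(rng.random() < probs[item]) for item in PATIENT_ITEMS}
            )
            iqcode = _sample_iqcode(rng, dists, params.missingness, params.latent_loading)
            records.append(
                CohortRecord(
                    patient=responses,
                    label=group,
                    iqcode=iqcode,
                    id=f"{prefix}{k + 1:04d}",
                )
            )
    return records


# ---------------------------------------------------------------------------
# Planted-cutoff scenario (parameter-recovery oracle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSubgroup:
    """One subgroup of a planted-cutoff cohort.

    ``assignments`` fixes the values of the subgroup-defining items;
    ``cutoff`` is the informant-mean threshold planted between the
    groups; ``patient_fraction`` sets the label mix (fractions must
    differ across subgroups for the tree fit to have a signal).
    """

    assignments: Mapping[str, bool]
    cutoff: float
    patient_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.assignments:
            raise InputError("a planted subgroup must fix at least one item")
        for item in self.assignments:
            if item not in PATIENT_ITEMS:
                raise InputError(f"unknown item {item!r}")
        if not 1.0 < self.cutoff < 5.0:
            raise InputError(f"planted cutoff must lie in (1, 5), got {self.cutoff!r}")
        if not 0.0 < self.patient_fraction < 1.0:
            raise InputError("patient_fraction must lie in (0, 1)")


#: Default planted structure: the two Q1=no subgroups of the published
#: algorithm with their printed cutoffs; the differing patient fractions
#: (0.5 mixed vs 0.15 low) give the tree fit its selection signal.
DEFAULT_PLANTED_SUBGROUPS: tuple[PlantedSubgroup, ...] = (
    PlantedSubgroup({"q1": False, "q2": True}, cutoff=3.07, patient_fraction=0.5),
    PlantedSubgroup({"q1": False, "q2": False}, cutoff=3.50, patient_fraction=0.15),
)

#: Items not fixed by a subgroup predicate: symptoms denied, clock correct.
_BENIGN_PROFILE = {q: False for q in PATIENT_ITEMS[:5]} | {c: True for c in PATIENT_ITEMS[5:]}


def _iqcode_items_for_mean(target: float, rng: np.random.Generator) -> IqcodeResponses:
    """Seven complete ratings whose mean is the 1/7-grid value nearest target."""
    total = int(round(7.0 * min(5.0, max(1.0, target))))
    total = min(35, max(7, total))
    base, rem = divmod(total, 7)
    values = [base + 1] * rem + [base] * (7 - rem)
    rng.shuffle(values)
    return IqcodeResponses(items=tuple(int(v) for v in values))


def planted_cutoff_scenario(
    subgroups: Sequence[PlantedSubgroup] = DEFAULT_PLANTED_SUBGROUPS,
    separation: float = 0.5,
    n_per_subgroup: int = 2000,
    seed: Optional[int] = None,
    spread: float = 0.12,
) -> list[CohortRecord]:
    """Cohort with known subgroup-specific informant cutoffs.

    Within each subgroup, informant severity is drawn from Gaussians
    centered ``separation/2`` below the planted cutoff for controls and
    above it for patients (standard deviation ``spread``), then
    converted to seven complete 1..5 ratings whose mean sits on the
    nearest 1/7 grid point.  At large n the CCR-optimal cutoff of the
    generated scores therefore lies within one candidate-grid step of
    the planted value.  ``separation = 0`` produces no signal (expected
    CCR about one half).
    """
    if separation < 0:
        raise InputError("separation must be non-negative")
    if spread <= 0:
        raise InputError("spread must be positive")
    if n_per_subgroup < 2:
        raise InputError("n_per_subgroup must be >= 2")
    seen = set()
    for sg in subgroups:
        key = tuple(sorted((k, v) for k, v in sg.assignments.items()))
        if key in seen:
            raise InputError("planted subgroups must have distinct assignments")
        seen.add(key)
        lo = sg.cutoff - separation / 2.0
        hi = sg.cutoff + separation / 2.0
        if lo < 1.0 or hi > 5.0:
            raise InputError(
                f"cutoff {sg.cutoff} with separation {separation} leaves the "
                "1..5 rating scale"
            )

    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    for si, sg in enumerate(subgroups):
        values = dict(_BENIGN_PROFILE)
        values.update(sg.assignments)
        responses = PatientResponses(**values)
        n_pat = int(round(n_per_subgroup * sg.patient_fraction))
        n_ctl = n_per_subgroup - n_pat
        for label, n, center in (
            (CONTROL, n_ctl, sg.cutoff - separation / 2.0),
            (PATIENT, n_pat, sg.cutoff + separation / 2.0),
        ):
            for k in range(n):
                target = rng.normal(center, spread)
                records.append(
                    CohortRecord(
                        patient=responses,
                        label=label,
                        iqcode=_iqcode_items_for_mean(target, rng),
                        id=f"sg{si}{label[0]}{k + 1:05d}",
                    )
                )
    return records
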