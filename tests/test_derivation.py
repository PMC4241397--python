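"""CART, contingency/subgroup analysis, ROC optimization and bootstrap."""

import itertools
import subprocess

import numpy as np
import pytest

from braincheck import (
    CartParams,
    Decision,
    DerivationWarning,
    bootstrap_evaluate,
    bootstrap_tree_stability,
    build_contingency,
    derive_combined_rules,
    evaluate_direct,
    find_homogeneous_subgroups,
    fit_cart,
    prune_noninformative,
    roc_optimal_cutoff,
    run_derivation,
)
from braincheck.derivation import ContingencyTable, homogeneity_class
from braincheck.instrument import PATIENT_ITEMS, InputError, Leaf, Split
from braincheck.metrics import CONTROL, PATIENT
from braincheck.simulate import (
    DEFAULT_PLANTED_SUBGROUPS,
    default_simulation_params,
    planted_cutoff_scenario,
    simulate_cohort,
)

FE = Decision.FURTHER_EVALUATION
WW = Decision.WATCHFUL_WAITING


def _random_cohort(make_record, rng, n, rule, items=PATIENT_ITEMS):
    """Cohort with iid Bernoulli(0.5) items and label = rule(values, rng)."""
    records = []
    for _ in range(n):
        values = {i: bool(rng.random() < 0.5) for i in items}
        label = PATIENT if rule(values, rng) else CONTROL
        records.append(make_record(label, iq=3, **values))
    return records


# ---------------------------------------------------------------------------
# fit_cart
# ---------------------------------------------------------------------------

def test_perfect_separator_yields_single_split(make_record):
    rng = np.random.default_rng(0)
    cohort = _random_cohort(make_record, rng, 40, lambda v, r: v["q1"])
    tree = fit_cart(cohort, PATIENT_ITEMS)
    assert isinstance(tree.root, Split) and tree.root.item == "q1"
    assert tree.items_used() == ("q1",)
    preds = [tree.decide(r.patient.as_dict()) for r in cohort]
    acc = np.mean([(p is FE) == (r.label == PATIENT) for p, r in zip(preds, cohort)])
    assert acc == 1.0


@pytest.mark.parametrize("cp", [1.0, 1.5])
def test_complexity_parameter_at_or_above_one_gives_stump(make_record, cp):
    rng = np.random.default_rng(1)
    cohort = _random_cohort(make_record, rng, 40, lambda v, r: v["q1"])
    tree = fit_cart(cohort, PATIENT_ITEMS, CartParams(complexity_parameter=cp))
    assert isinstance(tree.root, Leaf)


def test_single_class_cohort_warns_and_returns_stump(make_record):
    cohort = [make_record(PATIENT, q1=bool(i % 2)) for i in range(6)]
    with pytest.warns(DerivationWarning, match="single-class"):
        tree = fit_cart(cohort, PATIENT_ITEMS)
    assert isinstance(tree.root, Leaf)
    assert tree.root.decision is FE


def test_empty_item_set_rejected(make_record):
    with pytest.raises(InputError):
        fit_cart([make_record(PATIENT), make_record(CONTROL)], items=())


def _depth2_oracle_accuracy(cohort, items):
    """Best training accuracy of any tree of depth <= 2 (exhaustive search)."""
    X = {i: np.array([getattr(r.patient, i) for r in cohort]) for i in items}
    y = np.array([r.label == PATIENT for r in cohort])

    def leaf_correct(mask):
        if mask.sum() == 0:
            return 0
        n_pat = y[mask].sum()
        return max(n_pat, mask.sum() - n_pat)

    def best_child(mask, exclude):
        # best single split (or none) of the cases in `mask`
        best = leaf_correct(mask)
        for item in items:
            if item in exclude:
                continue
            yes = mask & X[item]
            no = mask & ~X[item]
            best = max(best, leaf_correct(yes) + leaf_correct(no))
        return best

    n = len(y)
    everyone = np.ones(n, dtype=bool)
    best = leaf_correct(everyone)
    for root in items:
        yes, no = X[root], ~X[root]
        best = max(best, best_child(yes, {root}) + best_child(no, {root}))
    return best / n


def test_planted_depth2_structure_recovered_vs_exhaustive_oracle(make_record):
    rng = np.random.default_rng(7)

    def rule(v, r):
        if not v["cdt5"]:
            p = 0.9
        elif v["q1"]:
            p = 0.85
        else:
            p = 0.1
        return r.random() < p

    cohort = _random_cohort(make_record, rng, 1000, rule)
    tree = fit_cart(cohort, PATIENT_ITEMS)
    assert set(tree.items_used()) == {"q1", "cdt5"}
    preds = [tree.decide(r.patient.as_dict()) for r in cohort]
    acc = np.mean([(p is FE) == (r.label == PATIENT) for p, r in zip(preds, cohort)])
    assert acc == pytest.approx(_depth2_oracle_accuracy(cohort, PATIENT_ITEMS))


def test_root_split_agrees_with_rpart(make_record, tmp_path):
    """The first split matches R's rpart on the same data (independent oracle)."""
    rng = np.random.default_rng(3)
    cohort = _random_cohort(
        make_record, rng, 200, lambda v, r: r.random() < (0.1 if v["cdt5"] else 0.9)
    )
    tree = fit_cart(cohort, PATIENT_ITEMS)
    csv = tmp_path / "cohort.csv"
    header = ",".join(("label", *PATIENT_ITEMS))
    lines = [header] + [
        ",".join(
            [r.label] + [str(int(getattr(r.patient, i))) for i in PATIENT_ITEMS]
        )
        for r in cohort
    ]
    csv.write_text("\n".join(lines) + "\n")
    script = (
        f"df <- read.csv('{csv}'); library(rpart); "
        "fit <- rpart(factor(label) ~ ., data=df, method='class', "
        "control=rpart.control(cp=0.01, minsplit=2, minbucket=1)); "
        "cat(as.character(fit$frame$var[1]))"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    assert tree.root.item == out.stdout.strip() == "cdt5"


# ---------------------------------------------------------------------------
# bootstrap_tree_stability
# ---------------------------------------------------------------------------

def test_perfect_separator_always_selected(make_record):
    rng = np.random.default_rng(2)
    cohort = _random_cohort(make_record, rng, 60, lambda v, r: v["q2"])
    freq = bootstrap_tree_stability(cohort, PATIENT_ITEMS, n_reps=100, seed=0)
    assert freq["q2"] == 1.0


def test_noise_items_rarely_selected(make_record):
    rng = np.random.default_rng(4)
    cohort = _random_cohort(make_record, rng, 500, lambda v, r: r.random() < 0.5)
    freq = bootstrap_tree_stability(cohort, PATIENT_ITEMS, n_reps=100, seed=1)
    assert all(f < 0.5 for f in freq.values())


def test_single_replicate_frequencies_are_binary(make_record):
    rng = np.random.default_rng(5)
    cohort = _random_cohort(make_record, rng, 50, lambda v, r: v["q1"])
    freq = bootstrap_tree_stability(cohort, PATIENT_ITEMS, n_reps=1, seed=2)
    assert set(freq.values()) <= {0.0, 1.0}
    with pytest.raises(InputError):
        bootstrap_tree_stability(cohort, PATIENT_ITEMS, n_reps=0, seed=2)


# ---------------------------------------------------------------------------
# Contingency table, pruning, subgroups
# ---------------------------------------------------------------------------

def test_contingency_four_records_four_cells(make_record):
    records = [
        make_record(PATIENT, q1=a, q2=b)
        for a, b in itertools.product([False, True], repeat=2)
    ]
    table = build_contingency(records, ("q1", "q2"))
    assert len(table.cells) == 4
    assert all(c + p == 1 for c, p in table.cells.values())
    assert table.n == 4  # conservation


def test_contingency_proportions_match_generator(make_record):
    params = default_simulation_params(n_control=1000, n_patient=1000)
    cohort = simulate_cohort(params, seed=11)
    table = build_contingency(cohort, ("q1",))
    p_ctl = params.endorsement[CONTROL]["q1"]
    p_pat = params.endorsement[PATIENT]["q1"]
    for value, (pc, pp) in ((True, (p_ctl, p_pat)), (False, (1 - p_ctl, 1 - p_pat))):
        n_c, n_p = table.cells[(value,)]
        expected = 1000 * pp / (1000 * pp + 1000 * pc)
        se = np.sqrt(expected * (1 - expected) / (n_c + n_p))
        assert abs(table.proportion((value,)) - expected) < 3 * se


def test_constant_item_pruned(make_record):
    records = [make_record(PATIENT, q1=True, cdt3=True) for _ in range(10)]
    records += [make_record(CONTROL, q1=False, cdt3=True) for _ in range(10)]
    table = build_contingency(records, ("q1", "cdt3"))
    assert prune_noninformative(table) == ("q1",)


def _cell_records(make_record, n_patient, n_control, **items):
    return [make_record(PATIENT, iq=4, **items) for _ in range(n_patient)] + [
        make_record(CONTROL, iq=2, **items) for _ in range(n_control)
    ]


def test_redundant_item_dropped_informative_item_kept(make_record):
    # cdt3 does not move any cell across a homogeneity threshold; q1 does.
    records = []
    records += _cell_records(make_record, 90, 10, q1=True, cdt3=True)
    records += _cell_records(make_record, 88, 12, q1=True, cdt3=False)
    records += _cell_records(make_record, 5, 95, q1=False, cdt3=True)
    records += _cell_records(make_record, 8, 92, q1=False, cdt3=False)
    table = build_contingency(records, ("q1", "cdt3"))
    assert prune_noninformative(table) == ("q1",)

    # an item flipping a subgroup across the threshold is retained
    records = []
    records += _cell_records(make_record, 90, 10, q1=True, cdt3=True)
    records += _cell_records(make_record, 50, 50, q1=True, cdt3=False)
    records += _cell_records(make_record, 5, 95, q1=False, cdt3=True)
    records += _cell_records(make_record, 8, 92, q1=False, cdt3=False)
    table = build_contingency(records, ("q1", "cdt3"))
    assert set(prune_noninformative(table)) == {"q1", "cdt3"}


def test_all_patient_cells_merge_into_one_high_subgroup(make_record):
    records = []
    for a, b in itertools.product([False, True], repeat=2):
        records += _cell_records(make_record, 10, 0, q1=a, q2=b)
    table = build_contingency(records, ("q1", "q2"))
    subgroups = find_homogeneous_subgroups(table)
    assert len(subgroups) == 1
    assert subgroups[0].homogeneity == "high"
    assert subgroups[0].patient_proportion == 1.0


def test_homogeneity_classes_at_default_thresholds():
    assert [homogeneity_class(p) for p in (0.05, 0.95, 0.5)] == ["low", "high", "mixed"]
    assert homogeneity_class(0.8) == "high"
    assert homogeneity_class(0.2) == "low"
    with pytest.raises(InputError):
        homogeneity_class(0.5, high_threshold=0.3, low_threshold=0.4)
    with pytest.raises(InputError):
        find_homogeneous_subgroups(
            ContingencyTable(items=("q1",), cells={(True,): (1, 1)}),
            high_threshold=0.5,
            low_threshold=0.5,
        )


def test_published_pattern_yields_four_subgroups(make_record):
    """Cells shaped like the instrument's derivation collapse to exactly four
    subgroups over (Q1, Q2, Q3, CDT-5)."""
    items = ("q1", "q2", "q3", "cdt5")
    records = []
    for combo in itertools.product([False, True], repeat=4):
        v = dict(zip(items, combo))
        if not v["q1"] and v["q2"]:
            n_pat, n_ctl = 5, 5  # mixed
        elif not v["q1"]:
            n_pat, n_ctl = 1, 9  # low
        elif not v["q2"] and not v["q3"] and v["cdt5"]:
            n_pat, n_ctl = 5, 5  # mixed singleton
        else:
            n_pat, n_ctl = 9, 1  # high
        records += _cell_records(make_record, n_pat, n_ctl, **v)
    table = build_contingency(records, items)
    subgroups = find_homogeneous_subgroups(table)
    assert len(subgroups) == 4
    by_class = sorted((s.homogeneity, len(s.cells)) for s in subgroups)
    assert by_class == [("high", 7), ("low", 4), ("mixed", 1), ("mixed", 4)]


# ---------------------------------------------------------------------------
# ROC cutoff optimization
# ---------------------------------------------------------------------------

def test_perfect_separation_cutoff_at_midpoint():
    r = roc_optimal_cutoff([3.0, 3.2, 3.4, 3.6], [CONTROL, CONTROL, PATIENT, PATIENT])
    assert r.cutoff == pytest.approx(3.3)
    assert (r.sensitivity, r.specificity, r.ccr) == (1.0, 1.0, 1.0)


def test_identical_scores_give_majority_ccr():
    r = roc_optimal_cutoff([3.0] * 10, [PATIENT] * 7 + [CONTROL] * 3)
    assert r.ccr == pytest.approx(0.7)


def test_single_class_rejected():
    with pytest.raises(InputError):
        roc_optimal_cutoff([1.0, 2.0], [PATIENT, PATIENT])


def _bruteforce_roc(scores, labels):
    scores = np.asarray(scores, float)
    y = np.array([l == PATIENT for l in labels])
    u = np.unique(scores)
    candidates = [u[0]] + [(a + b) / 2 for a, b in zip(u[:-1], u[1:])]
    candidates.append(np.nextafter(u[-1], np.inf))
    best_ccr, best_cut = -1.0, None
    for c in candidates:  # ascending: ties keep the lowest cutoff
        pos = scores >= c
        ccr = ((pos & y).sum() + (~pos & ~y).sum()) / y.size
        if ccr > best_ccr + 1e-12:
            best_ccr, best_cut = ccr, c
    return best_cut, best_ccr


@pytest.mark.parametrize("seed", range(20))
def test_roc_equals_bruteforce_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = 50
    labels = [PATIENT if rng.random() < 0.5 else CONTROL for _ in range(n)]
    scores = rng.normal([3.5 if l == PATIENT else 3.0 for l in labels], 0.4)
    scores = np.clip(np.round(scores, 2), 1, 5)
    r = roc_optimal_cutoff(scores, labels)
    cut, ccr = _bruteforce_roc(scores, labels)
    assert r.cutoff == pytest.approx(cut)
    assert r.ccr == pytest.approx(ccr)


def test_roc_invariant_to_monotone_score_transform():
    rng = np.random.default_rng(9)
    labels = [PATIENT if rng.random() < 0.5 else CONTROL for _ in range(40)]
    scores = rng.normal([3.6 if l == PATIENT else 3.0 for l in labels], 0.5)
    r1 = roc_optimal_cutoff(scores, labels)
    r2 = roc_optimal_cutoff(np.exp(scores), labels)
    assert (r1.sensitivity, r1.specificity, r1.ccr) == (
        r2.sensitivity, r2.specificity, r2.ccr,
    )
    # same partition of subjects
    assert np.array_equal(scores >= r1.cutoff, np.exp(scores) >= r2.cutoff)


# ---------------------------------------------------------------------------
# derive_combined_rules
# ---------------------------------------------------------------------------

def test_planted_cutoffs_recovered_within_half_grid_step():
    cohort = planted_cutoff_scenario(seed=1)
    rules = derive_combined_rules(cohort)
    assert rules.provenance == "derived"
    for planted in DEFAULT_PLANTED_SUBGROUPS:
        rule = rules.subgroup_for(
            {i: planted.assignments.get(i, False) for i in rules.items}
        )
        assert rule.cutoff is not None
        assert abs(rule.cutoff - planted.cutoff) <= 0.05


def test_perfectly_separable_cohort_reaches_training_ccr_one(make_record):
    cohort = [make_record(PATIENT, iq=4, q1=True, id=f"p{i}") for i in range(30)]
    cohort += [make_record(CONTROL, iq=2, q1=False, id=f"c{i}") for i in range(30)]
    with pytest.warns(DerivationWarning):
        report = run_derivation(cohort)
    metrics = evaluate_direct(report.rules, report.tree, cohort)
    assert metrics.ccr == 1.0


def test_unobserved_combinations_default_to_watchful_waiting(make_record):
    cohort = []
    cohort += _cell_records(make_record, 36, 4, q1=True, q2=True)
    cohort += _cell_records(make_record, 4, 36, q1=True, q2=False)
    cohort += _cell_records(make_record, 12, 28, q1=False, q2=True)
    # (q1=no, q2=no) never occurs
    with pytest.warns(DerivationWarning, match="unobserved"):
        report = run_derivation(cohort)
    assert set(report.items_retained) == {"q1", "q2"}
    default_rule = report.rules.subgroup_for({"q1": False, "q2": False})
    assert default_rule.decision is WW
    assert "unobserved" in default_rule.description


def test_derivation_rules_always_partition(make_record):
    for seed in (0, 3):
        cohort = planted_cutoff_scenario(seed=seed, n_per_subgroup=400)
        rules = derive_combined_rules(cohort)
        for combo in itertools.product([False, True], repeat=len(rules.items)):
            assert sum(r.matches(combo) for r in rules.rules) == 1


# ---------------------------------------------------------------------------
# bootstrap_evaluate
# ---------------------------------------------------------------------------

def _simulated_setup(seed=5):
    from braincheck import default_rule_set, default_tree

    cohort = simulate_cohort(default_simulation_params(), seed=seed)
    usable = [r for r in cohort if (s := r.iqcode_score()) is not None and s.valid]
    return default_rule_set(), default_tree(), usable


def test_perfect_rules_give_unit_rates_in_every_replicate(make_record):
    cohort = [make_record(PATIENT, iq=5, q1=True, id=f"p{i}") for i in range(10)]
    cohort += [make_record(CONTROL, iq=1, q1=False, id=f"c{i}") for i in range(10)]
    rules = derive_combined_rules(cohort)
    from braincheck import fit_cart

    tree = fit_cart(cohort)
    s = bootstrap_evaluate(rules, tree, cohort, n_reps=50, seed=3)
    assert np.all(s.sensitivity == 1.0)
    assert np.all(s.specificity == 1.0)
    assert np.all(s.ccr == 1.0)


def test_single_replicate_equals_direct_metrics_on_that_resample():
    rules, tree, cohort = _simulated_setup()
    seed = 17
    s = bootstrap_evaluate(rules, tree, cohort, n_reps=1, seed=seed)
    idx = np.random.default_rng(seed).integers(0, len(cohort), len(cohort))
    direct = evaluate_direct(rules, tree, [cohort[i] for i in idx])
    assert s.sensitivity[0] == pytest.approx(direct.sensitivity)
    assert s.specificity[0] == pytest.approx(direct.specificity)
    assert s.ccr[0] == pytest.approx(direct.ccr)


def test_bootstrap_means_converge_to_full_sample_metrics():
    rules, tree, cohort = _simulated_setup()
    direct = evaluate_direct(rules, tree, cohort)
    s = bootstrap_evaluate(rules, tree, cohort, n_reps=5000, seed=8)
    for name, target in (
        ("sensitivity", direct.sensitivity),
        ("specificity", direct.specificity),
        ("ccr", direct.ccr),
    ):
        values = getattr(s, name)
        mc_se = np.nanstd(values) / np.sqrt(np.sum(~np.isnan(values)))
        assert abs(np.nanmean(values) - target) < 3 * mc_se


def test_replicates_missing_a_class_are_excluded_and_counted(make_record):
    cohort = [make_record(PATIENT, iq=5, q1=True, id="p0")]
    cohort += [make_record(CONTROL, iq=1, q1=False, id=f"c{i}") for i in range(9)]
    tiny = CartParams(min_node_size=2)
    rules, tree = derive_combined_rules(cohort, tiny), fit_cart(cohort, params=tiny)
    s = bootstrap_evaluate(rules, tree, cohort, n_reps=300, seed=4)
    n_nan = int(np.isnan(s.sensitivity).sum())
    assert n_nan > 0  # P(no patient in a replicate) = 0.9^10 ~ 0.35
    assert s.to_dict()["sensitivity"]["n_undefined"] == n_nan
    assert not np.isnan(s.ccr).any()


def test_stratified_resampling_keeps_both_classes():
    rules, tree, cohort = _simulated_setup(seed=6)
    s = bootstrap_evaluate(rules, tree, cohort, n_reps=100, seed=0, stratified=True)
    assert not np.isnan(s.sensitivity).any()
    assert not np.isnan(s.specificity).any()
    with pytest.raises(InputError):
        bootstrap_evaluate(rules, tree, cohort, n_reps=0, seed=0)


def test_quartile_range_format_matches_reporting_style():
    rules, tree, cohort = _simulated_setup()
    s = bootstrap_evaluate(rules, tree, cohort, n_reps=200, seed=9)
    line = s.format_line("sensitivity")
    assert line.startswith("mean sensitivity of ")
    assert "(quartile range: " in line and line.endswith("%)")
    lo, hi = s.quartile_range("sensitivity")
    assert lo <= hi
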