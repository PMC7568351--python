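"""Rule indicators, FP-growth vs. the exhaustive oracle, and rule derivation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from comorbnet.mining import (AssociationRule, Thresholds,
                              UndefinedStatisticError, brute_force_itemsets,
                              confidence, derive_rules, lift,
                              mine_frequent_itemsets, mine_rules,
                              min_support_count, read_rules, support,
                              support_count, write_rules)
from comorbnet.preprocessing import TransactionDB

from conftest import make_db


def as_set(itemsets):
    return {(s.items, s.support_count) for s in itemsets}


# ------------------------------------------------------------- indicators

def test_support_by_direct_counting(worked_db):
    assert support({"A", "C"}, worked_db) == pytest.approx(2 / 3)
    assert support({"A"}, worked_db) == pytest.approx(2 / 3)
    assert support({"Q"}, worked_db) == 0.0


def test_anchor_present_everywhere_has_support_one():
    db = make_db([{"F84", "X"}, {"F84"}, {"F84", "Y"}])
    assert support({"F84"}, db) == 1.0


def test_confidence_from_counts(worked_db):
    assert confidence("A", "C", worked_db) == 1.0
    assert confidence("C", "D", worked_db) == 0.0
    with pytest.raises(UndefinedStatisticError):
        confidence("Q", "A", worked_db)


def test_lift_value_and_symmetry(worked_db):
    assert lift("A", "C", worked_db) == pytest.approx(1.5)
    assert lift("A", "C", worked_db) == lift("C", "A", worked_db)
    with pytest.raises(UndefinedStatisticError):
        lift("Q", "A", worked_db)


def test_empty_itemset_support_is_an_error(worked_db):
    with pytest.raises(ValueError):
        support(set(), worked_db)


# --------------------------------------------------------------- FP-growth

def test_worked_example_itemsets_at_count_two(worked_db):
    found = mine_frequent_itemsets(worked_db, min_sup=2 / 3)
    expected = {(frozenset("A"), 2), (frozenset("B"), 2),
                (frozenset("C"), 2), (frozenset({"A", "C"}), 2)}
    assert as_set(found) == expected


def test_threshold_above_everything_gives_nothing(worked_db):
    assert mine_frequent_itemsets(worked_db, min_sup=0.99) == []


def test_single_transaction_power_set():
    db = make_db([{"X", "Y"}])
    found = mine_frequent_itemsets(db, min_sup=1.0)
    assert {s.items for s in found} == {frozenset("X"), frozenset("Y"),
                                        frozenset({"X", "Y"})}


def test_invalid_min_sup_rejected(worked_db):
    for bad in (0, -0.1, 1.5):
        with pytest.raises(ValueError):
            mine_frequent_itemsets(worked_db, bad)


def test_output_independent_of_transaction_order(worked_db):
    reversed_db = TransactionDB(dict(reversed(list(worked_db.transactions.items()))))
    assert as_set(mine_frequent_itemsets(worked_db, 1 / 3)) == \
        as_set(mine_frequent_itemsets(reversed_db, 1 / 3))


transactions_strategy = st.lists(
    st.sets(st.sampled_from([f"I{i}" for i in range(12)]), min_size=1, max_size=8),
    min_size=1, max_size=25)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(transactions=transactions_strategy,
       min_sup=st.floats(min_value=0.05, max_value=1.0))
def test_fp_growth_equals_brute_force(transactions, min_sup):
    """FP-growth and exhaustive enumeration find the same frequent sets."""
    db = make_db(transactions)
    assert as_set(mine_frequent_itemsets(db, min_sup)) == \
        as_set(brute_force_itemsets(db, min_sup))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(transactions=transactions_strategy)
def test_downward_closure(transactions):
    db = make_db(transactions)
    found = mine_frequent_itemsets(db, 0.2)
    frequent = {s.items for s in found}
    min_count = min_support_count(0.2, db.n_patients)
    for s in frequent:
        for item in s:
            if len(s) > 1:
                assert s - {item} in frequent
        assert support_count(s, db) >= min_count


@settings(max_examples=40, deadline=None, derandomize=True)
@given(transactions=transactions_strategy,
       lo=st.floats(min_value=0.05, max_value=0.5),
       hi=st.floats(min_value=0.5, max_value=1.0))
def test_raising_min_sup_never_adds_itemsets(transactions, lo, hi):
    db = make_db(transactions)
    at_hi = {s.items for s in mine_frequent_itemsets(db, hi)}
    at_lo = {s.items for s in mine_frequent_itemsets(db, lo)}
    assert at_hi <= at_lo


def test_oracle_guard_on_large_universe():
    db = make_db([{f"I{i}"} for i in range(25)])
    with pytest.raises(ValueError):
        brute_force_itemsets(db, 0.01)


# -------------------------------------------------------------------- rules

def test_worked_example_rules(worked_db):
    itemsets = mine_frequent_itemsets(worked_db, 2 / 3)
    rb = derive_rules(itemsets, worked_db, Thresholds(2 / 3, 0.0, 1.0))
    pairs = {(r.antecedent, r.consequent): r for r in rb}
    assert set(pairs) == {("A", "C"), ("C", "A")}
    assert pairs[("A", "C")].conf == 1.0
    assert pairs[("A", "C")].lift == pytest.approx(1.5)


def test_lift_exactly_one_is_excluded():
    # A and B independent by construction: P(A)=P(B)=1/2, P(AB)=1/4
    db = make_db([{"A", "B"}, {"A"}, {"B"}, {"Z"}])
    rb = mine_rules(db, Thresholds(0.01, 0.0, 1.0))
    assert ("A", "B") not in {(r.antecedent, r.consequent) for r in rb}


def test_rule_identity_chain(small_cohort_db):
    """conf = sup/sup(A) and lift = conf/sup(B), recomputed from the db."""
    rb = mine_rules(small_cohort_db, Thresholds(0.01, 0.0, 1.0))
    assert len(rb) > 0
    for r in rb:
        assert r.conf == pytest.approx(
            r.sup / support({r.antecedent}, small_cohort_db), abs=1e-12)
        assert r.lift == pytest.approx(
            r.conf / support({r.consequent}, small_cohort_db), abs=1e-12)


def test_raising_thresholds_never_adds_rules(small_cohort_db):
    base = mine_rules(small_cohort_db, Thresholds(0.005, 0.0, 1.0))
    for t in (Thresholds(0.02, 0.0, 1.0), Thresholds(0.005, 0.3, 1.0),
              Thresholds(0.005, 0.0, 1.5)):
        tighter = mine_rules(small_cohort_db, t)
        assert {(r.antecedent, r.consequent) for r in tighter} <= \
            {(r.antecedent, r.consequent) for r in base}


def test_planted_pairs_recovered_at_study_thresholds():
    """All planted pairs appear (as their generalized items) in the mined
    rule base at the standard thresholds (sup 0.001, conf 0, lift > 1) on a
    2000-patient cohort."""
    from comorbnet import (build_generalization_map, build_transactions,
                           exclude_chapters, filter_patients, generate_cohort,
                           planted_truth)
    from comorbnet.synthetic import CohortConfig

    cfg = CohortConfig(n_patients=2000, seed=42)
    records = generate_cohort(cfg)
    kept = exclude_chapters(records)
    gmap = build_generalization_map({r.icd10_code for r in kept})
    db = filter_patients(build_transactions(kept, gmap))
    rb = mine_rules(db, Thresholds(0.001, 0.0, 1.0))
    mined = {(r.antecedent, r.consequent): r for r in rb}
    for planted in planted_truth(cfg):
        a, b = gmap.item(planted.antecedent), gmap.item(planted.consequent)
        assert (a, b) in mined, (a, b)


def test_rule_csv_roundtrip(tmp_path, small_cohort_db):
    rb = mine_rules(small_cohort_db, Thresholds(0.01, 0.0, 1.0))
    path = tmp_path / "rules.csv"
    write_rules(rb, path)
    back = read_rules(path)
    assert [(r.antecedent, r.consequent, r.support_count) for r in back] == \
        [(r.antecedent, r.consequent, r.support_count) for r in rb]
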