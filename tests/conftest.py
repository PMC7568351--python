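import pytest

from comorbnet.mining import AssociationRule
from comorbnet.preprocessing import TransactionDB

WORKED_RULE_PAIRS = [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("C", "E")]
WORKED_PATIENTS = {
    "P1": frozenset("ABC"),
    "P2": frozenset("BD"),
    "P3": frozenset("ACE"),
}


@pytest.fixture
def worked_rules():
    """The five-rule hypothesized rule base of the evaluation walkthrough."""
    return [AssociationRule(a, b, support_count=1, sup=0.5, conf=0.5, lift=1.5)
            for a, b in WORKED_RULE_PAIRS]


@pytest.fixture
def worked_db():
    """The three-patient case set {ABC, BD, ACE}."""
    return TransactionDB(dict(WORKED_PATIENTS))


def make_db(transactions):
    """Build a TransactionDB from an iterable of item iterables."""
    return TransactionDB({f"P{i + 1}": frozenset(t)
                          for i, t in enumerate(transactions)})


@pytest.fixture(scope="session")
def small_cohort_db():
    """A 400-patient synthetic cohort run through the preprocessing chain."""
    from comorbnet import (build_generalization_map, build_transactions,
                           exclude_chapters, filter_patients, generate_cohort)
    from comorbnet.synthetic import CohortConfig

    records = generate_cohort(CohortConfig(n_patients=400, seed=7))
    kept = exclude_chapters(records)
    gmap = build_generalization_map({r.icd10_code for r in kept})
    db = build_transactions(kept, gmap)
    return filter_patients(db)
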