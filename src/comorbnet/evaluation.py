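"""Disease-frequency-stratified k-fold grouping and the rule-prediction
metric suite.

Evaluation walks every disease d of a test patient and *triggers* every rule
whose antecedent is d.  A trigger is correct iff the rule's consequent is
also among the patient's diseases.  Per patient this yields

    Pt / Pf   — counts of correct / incorrect triggers,
    Prt / Prf — Pt (Pf) divided by the patient's disease count,
    Pdt / Pdf — distinct correctly (incorrectly) predicted diseases over the
                disease count; "predicted" means appearing as a triggered
                consequent — the examined antecedent itself never counts,
    Pn        — fraction of actual diseases never predicted (Pdt + Pn = 1).

Per fold, triggers are summed, the sets R1 / R2 of rules with at least one
correct / incorrect prediction are unioned across patients (a rule can be in
both), and

    Nrt = |R1|, Nrf = |R2|, Nrn = Tr - |R1 u R2|,
    Rt = Pt / Nrt, Rf = Pf / Nrf   (tagged undefined when the denominator
                                    is zero — never reported as 0),
    AP* = arithmetic means of the per-patient ratios.

Fold assignment stratifies by disease frequency: diseases are processed
rarest first, and each disease's still-unassigned patients are shuffled and
placed one by one into a uniformly random group among those of minimal
current size, which guarantees a group-size spread of at most one.

All ratios are exact :class:`fractions.Fraction` values internally and are
rendered as decimals only on output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mining import AssociationRule, RuleBase, Thresholds, mine_rules
from .preprocessing import TransactionDB

RulePair = tuple[str, str]


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    groups: tuple[frozenset[str], ...]
    seed: int

    def test_train(self, i: int, db: TransactionDB) -> tuple[TransactionDB, TransactionDB]:
        test_ids = self.groups[i]
        test = TransactionDB({p: t for p, t in db.transactions.items() if p in test_ids})
        train = TransactionDB({p: t for p, t in db.transactions.items() if p not in test_ids})
        return test, train


def assign_folds(db: TransactionDB, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Disease-frequency-stratified partition of patients into k groups."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > db.n_patients:
        raise ValueError(f"k={k} exceeds the {db.n_patients} available patients")
    rng = random.Random(seed)
    freq = db.item_frequencies
    # rarest disease first; lexicographic tie-break for determinism
    disease_queue = sorted(freq, key=lambda d: (freq[d], d))
    unassigned = set(db.transactions)
    groups: list[set[str]] = [set() for _ in range(k)]
    for disease in disease_queue:
        batch = sorted(p for p in unassigned
                       if disease in db.transactions[p])
        if not batch:
            continue
        rng.shuffle(batch)
        for pid in batch:
            min_size = min(len(g) for g in groups)
            candidates = [i for i, g in enumerate(groups) if len(g) == min_size]
            groups[rng.choice(candidates)].add(pid)
        unassigned -= set(batch)
    return FoldAssignment(k, tuple(frozenset(g) for g in groups), seed)


def filter_rules(rulebase: RuleBase, C: float) -> RuleBase:
    """Keep rules with conf >= C; the retained count is Tr."""
    if not 0 <= C <= 1:
        raise ValueError(f"confidence cutoff must be in [0,1], got {C}")
    return RuleBase(tuple(r for r in rulebase.rules if r.conf >= C),
                    rulebase.thresholds, rulebase.n_transactions)


@dataclass(frozen=True)
class PatientEvaluation:
    patient_id: str
    Pt: int
    Pf: int
    correct_rules: frozenset[RulePair]
    incorrect_rules: frozenset[RulePair]
    predicted: frozenset[str]
    Prt: Fraction
    Prf: Fraction
    Pdt: Fraction
    Pdf: Fraction
    Pn: Fraction
    #: per examined disease: (correct triggers, incorrect triggers)
    trigger_detail: Mapping[str, tuple[int, int]] = field(default_factory=dict)


def evaluate_patient(patient_id: str, diseases: frozenset[str] | set[str],
                     rules: Sequence[AssociationRule] | RuleBase) -> PatientEvaluation:
    """Trigger every rule whose antecedent is one of the patient's diseases
    and score the predictions against the patient's actual disease set.
    """
    diseases = frozenset(diseases)
    if not diseases:
        raise ValueError("patient has no diseases")
    by_antecedent: dict[str, list[AssociationRule]] = {}
    for r in rules:
        by_antecedent.setdefault(r.antecedent, []).append(r)

    Pt = Pf = 0
    correct: set[RulePair] = set()
    incorrect: set[RulePair] = set()
    predicted: set[str] = set()
    detail: dict[str, tuple[int, int]] = {}
    for d in sorted(diseases):
        d_correct = d_incorrect = 0
        for r in by_antecedent.get(d, ()):
            predicted.add(r.consequent)
            if r.consequent in diseases:
                d_correct += 1
                correct.add((r.antecedent, r.consequent))
            else:
                d_incorrect += 1
                incorrect.add((r.antecedent, r.consequent))
        detail[d] = (d_correct, d_incorrect)
        Pt += d_correct
        Pf += d_incorrect

    n = len(diseases)
    return PatientEvaluation(
        patient_id=patient_id, Pt=Pt, Pf=Pf,
        correct_rules=frozenset(correct), incorrect_rules=frozenset(incorrect),
        predicted=frozenset(predicted),
        Prt=Fraction(Pt, n), Prf=Fraction(Pf, n),
        Pdt=Fraction(len(predicted & diseases), n),
        Pdf=Fraction(len(predicted - diseases), n),
        Pn=Fraction(len(diseases - predicted), n),
        trigger_detail=detail,
    )


UNDEFINED = None  # tagged missing value for zero-denominator Rt/Rf


@dataclass(frozen=True)
class FoldEvaluation:
    C: float
    Tr: int
    Np: int
    Pt: int
    Pf: int
    Nrt: int
    Nrf: int
    Nrn: int
    Rt: Fraction | None
    Rf: Fraction | None
    APrt: Fraction
    APrf: Fraction
    APdt: Fraction
    APdf: Fraction
    APn: Fraction


def aggregate_fold(patient_evals: Sequence[PatientEvaluation], Tr: int,
                   C: float = 0.0) -> FoldEvaluation:
    """Fold-level totals, rule-set sizes, and patient-averaged ratios."""
    if not patient_evals:
        raise ValueError("fold contains no evaluated patients")
    Np = len(patient_evals)
    Pt = sum(e.Pt for e in patient_evals)
    Pf = sum(e.Pf for e in patient_evals)
    R1: set[RulePair] = set().union(*(e.correct_rules for e in patient_evals))
    R2: set[RulePair] = set().union(*(e.incorrect_rules for e in patient_evals))
    Nrt, Nrf = len(R1), len(R2)
    Nrn = Tr - len(R1 | R2)

    def mean(attr: str) -> Fraction:
        return sum((getattr(e, attr) for e in patient_evals), Fraction(0)) / Np

    return FoldEvaluation(
        C=C, Tr=Tr, Np=Np, Pt=Pt, Pf=Pf, Nrt=Nrt, Nrf=Nrf, Nrn=Nrn,
        Rt=Fraction(Pt, Nrt) if Nrt else UNDEFINED,
        Rf=Fraction(Pf, Nrf) if Nrf else UNDEFINED,
        APrt=mean("Prt"), APrf=mean("Prf"),
        APdt=mean("Pdt"), APdf=mean("Pdf"), APn=mean("Pn"),
    )


def evaluate_fold(test_db: TransactionDB, rulebase: RuleBase,
                  C: float = 0.0) -> FoldEvaluation:
    """Filter the rule base at C and evaluate every patient of the test fold."""
    filtered = filter_rules(rulebase, C)
    evals = [evaluate_patient(pid, items, filtered)
             for pid, items in sorted(test_db.transactions.items())]
    return aggregate_fold(evals, Tr=len(filtered), C=C)


REPORT_FIELDS = ["Tr", "Pt", "Nrt", "Rt", "Np", "APrt", "APdt",
                 "Pf", "Nrf", "Rf", "APrf", "APdf", "Nrn", "APn"]


def cross_validate(db: TransactionDB,
                   k: int = 10,
                   C_grid: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(11)),
                   seed: int = 0,
                   miner: Callable[[TransactionDB], RuleBase] | None = None,
                   ) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the mined rule base.

    For each fold, rules are mined on the training patients only (``miner``
    defaults to FP-growth at the standard thresholds), then filtered and
    evaluated on the held-out fold at every confidence cutoff in ``C_grid``.
    Returns one row per C with the mean and standard deviation (population,
    over the k folds) of every fold-level metric.
    """
    if miner is None:
        miner = lambda train: mine_rules(train, Thresholds())
    folds = assign_folds(db, k=k, seed=seed)
    per_fold: dict[float, list[FoldEvaluation]] = {C: [] for C in C_grid}
    for i in range(k):
        test, train = folds.test_train(i, db)
        if test.n_patients == 0:
            raise ValueError(f"fold {i} has no test patients")
        rulebase = miner(train)
        for C in C_grid:
            per_fold[C].append(evaluate_fold(test, rulebase, C))

    rows = []
    for C in C_grid:
        row: dict[str, float] = {"C": C}
        for name in REPORT_FIELDS:
            vals = [getattr(e, name) for e in per_fold[C]]
            defined = np.array([float(v) for v in vals if v is not None])
            row[f"{name}_mean"] = float(defined.mean()) if defined.size else float("nan")
            row[f"{name}_std"] = float(defined.std()) if defined.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
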