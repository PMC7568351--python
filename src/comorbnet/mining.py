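"""Frequent-itemset mining (FP-growth) and directed pairwise association rules.

The three rule indicators over a transaction database T are

    sup(A => B)  = P(A u B)          (fraction of transactions with both)
    conf(A => B) = sup_count(A u B) / sup_count(A)
    lift(A, B)   = P(A u B) / (P(A) P(B))

Mining builds a frequency-ordered FP-tree (shared prefix paths with node
counts) and recurses over conditional pattern bases; a brute-force subset
enumerator with the same contract serves as an independent oracle on small
universes.  Rules are single-antecedent, single-consequent: every frequent
2-itemset {a, b} yields a=>b and/or b=>a when support and confidence clear
their (inclusive) thresholds and lift clears its strict one — lift exactly 1
is independence and indicates no comorbidity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .preprocessing import TransactionDB


class UndefinedStatisticError(ZeroDivisionError):
    """A rule statistic is undefined because a marginal support is zero."""


def _counts(db: TransactionDB, itemsets: Iterable[frozenset[str]]) -> dict[frozenset[str], int]:
    counts = {s: 0 for s in itemsets}
    for items in db.transactions.values():
        for s in counts:
            if s <= items:
                counts[s] += 1
    return counts


def support_count(items: Iterable[str], db: TransactionDB) -> int:
    target = frozenset(items)
    if not target:
        raise ValueError("support of the empty itemset is not defined here")
    return sum(1 for t in db.transactions.values() if target <= t)


def support(items: Iterable[str], db: TransactionDB) -> float:
    """Fraction of transactions containing every item in ``items``."""
    if db.n_patients == 0:
        raise ValueError("empty transaction database")
    return support_count(items, db) / db.n_patients


def confidence(antecedent: str, consequent: str, db: TransactionDB) -> float:
    """sup_count({antecedent, consequent}) / sup_count({antecedent})."""
    denom = support_count([antecedent], db)
    if denom == 0:
        raise UndefinedStatisticError(f"antecedent {antecedent!r} has zero support")
    return support_count([antecedent, consequent], db) / denom


def lift(a: str, b: str, db: TransactionDB) -> float:
    """P(A u B) / (P(A) P(B)); symmetric in its arguments."""
    sa = support([a], db)
    sb = support([b], db)
    if sa == 0 or sb == 0:
        raise UndefinedStatisticError("lift undefined: zero marginal support")
    return support([a, b], db) / (sa * sb)


@dataclass(frozen=True, order=True)
class FrequentItemset:
    items: frozenset[str] = field(compare=False)
    support_count: int
    support: float

    def __post_init__(self):
        object.__setattr__(self, "items", frozenset(self.items))


def min_support_count(min_sup: float, n_transactions: int) -> int:
    """Convert a fractional threshold to an integer count by ceiling."""
    return max(1, math.ceil(min_sup * n_transactions))


# --------------------------------------------------------------------------
# FP-tree

class _FPNode:
    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item: str | None, parent: "_FPNode | None"):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _FPNode] = {}
        self.link: _FPNode | None = None


class _FPTree:
    """Prefix tree over frequency-ordered transactions with a header table.

    Items are ordered by descending frequency, ties broken lexicographically,
    so the tree shape is deterministic regardless of transaction order.
    """

    def __init__(self, transactions: Iterable[tuple[Sequence[str], int]],
                 item_counts: Mapping[str, int], min_count: int):
        self.min_count = min_count
        frequent = {it: c for it, c in item_counts.items() if c >= min_count}
        self.order = {it: i for i, it in enumerate(
            sorted(frequent, key=lambda it: (-frequent[it], it)))}
        self.root = _FPNode(None, None)
        self.header: dict[str, _FPNode] = {}
        for items, weight in transactions:
            ordered = sorted((it for it in set(items) if it in self.order),
                             key=self.order.__getitem__)
            self._insert(ordered, weight)

    def _insert(self, ordered_items: Sequence[str], weight: int) -> None:
        node = self.root
        for item in ordered_items:
            child = node.children.get(item)
            if child is None:
                child = _FPNode(item, node)
                node.children[item] = child
                child.link = self.header.get(item)
                self.header[item] = child
            child.count += weight
            node = child

    def prefix_paths(self, item: str) -> list[tuple[list[str], int]]:
        """Conditional pattern base of ``item``: (path above node, node count)."""
        paths = []
        node = self.header.get(item)
        while node is not None:
            path = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path or node.count:
                paths.append((path[::-1], node.count))
            node = node.link
        return paths


def _fp_mine(tree: _FPTree, suffix: frozenset[str],
             out: dict[frozenset[str], int]) -> None:
    # Visit header items rarest-first so each conditional tree is small.
    for item in sorted(tree.order, key=tree.order.__getitem__, reverse=True):
        count = 0
        node = tree.header.get(item)
        while node is not None:
            count += node.count
            node = node.link
        if count < tree.min_count:
            continue
        itemset = suffix | {item}
        out[itemset] = count
        base = tree.prefix_paths(item)
        cond_counts: dict[str, int] = {}
        for path, c in base:
            for it in path:
                cond_counts[it] = cond_counts.get(it, 0) + c
        cond_tree = _FPTree(base, cond_counts, tree.min_count)
        if cond_tree.order:
            _fp_mine(cond_tree, itemset, out)


def mine_frequent_itemsets(db: TransactionDB, min_sup: float) -> list[FrequentItemset]:
    """All itemsets with support >= ``min_sup``, via FP-growth."""
    if not 0 < min_sup <= 1:
        raise ValueError(f"min_sup must be in (0,1], got {min_sup}")
    n = db.n_patients
    if n == 0:
        return []
    min_count = min_support_count(min_sup, n)
    item_counts = db.item_frequencies
    tree = _FPTree(((items, 1) for items in db.transactions.values()),
                   item_counts, min_count)
    found: dict[frozenset[str], int] = {}
    _fp_mine(tree, frozenset(), found)
    return sorted((FrequentItemset(s, c, c / n) for s, c in found.items()),
                  key=lambda f: (len(f.items), sorted(f.items)))


def brute_force_itemsets(db: TransactionDB, min_sup: float,
                         max_universe: int = 20) -> list[FrequentItemset]:
    """Exhaustive-enumeration oracle with the same contract as
    :func:`mine_frequent_itemsets`; guarded to small item universes.
    """
    if not 0 < min_sup <= 1:
        raise ValueError(f"min_sup must be in (0,1], got {min_sup}")
    n = db.n_patients
    if n == 0:
        return []
    universe = sorted(db.items)
    if len(universe) > max_universe:
        raise ValueError(f"item universe of {len(universe)} exceeds the "
                         f"oracle guard of {max_universe}")
    min_count = min_support_count(min_sup, n)
    out = []
    for k in range(1, len(universe) + 1):
        found_at_k = False
        for combo in combinations(universe, k):
            c = support_count(combo, db)
            if c >= min_count:
                out.append(FrequentItemset(frozenset(combo), c, c / n))
                found_at_k = True
        if not found_at_k:
            break  # downward closure: no larger set can be frequent
    return sorted(out, key=lambda f: (len(f.items), sorted(f.items)))


# --------------------------------------------------------------------------
# Rules

@dataclass(frozen=True)
class AssociationRule:
    """Directed single-antecedent, single-consequent rule with its scores."""

    antecedent: str
    consequent: str
    support_count: int
    sup: float
    conf: float
    lift: float

    def __post_init__(self):
        if self.antecedent == self.consequent:
            raise ValueError("antecedent and consequent must differ")


@dataclass(frozen=True)
class Thresholds:
    min_sup: float = 0.001
    min_conf: float = 0.0
    min_lift: float = 1.0


@dataclass(frozen=True)
class RuleBase:
    rules: tuple[AssociationRule, ...]
    thresholds: Thresholds
    n_transactions: int

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def derive_rules(itemsets: Sequence[FrequentItemset], db: TransactionDB,
                 thresholds: Thresholds = Thresholds()) -> RuleBase:
    """Directed rules from frequent 2-itemsets.

    sup and conf gates are inclusive (>=); the lift gate is strict (>).
    Both directions of a pair are emitted when each passes on its own.
    """
    n = db.n_patients
    min_count = min_support_count(thresholds.min_sup, n)
    singles = {next(iter(f.items)): f.support_count
               for f in itemsets if len(f.items) == 1}
    rules: list[AssociationRule] = []
    for f in itemsets:
        if len(f.items) != 2 or f.support_count < min_count:
            continue
        a, b = sorted(f.items)
        pair_lift = (f.support_count * n) / (singles[a] * singles[b])
        if pair_lift <= thresholds.min_lift:
            continue
        for ant, cons in ((a, b), (b, a)):
            conf = f.support_count / singles[ant]
            if conf >= thresholds.min_conf:
                rules.append(AssociationRule(
                    antecedent=ant, consequent=cons,
                    support_count=f.support_count, sup=f.support,
                    conf=conf, lift=pair_lift))
    rules.sort(key=lambda r: (-r.conf, -r.lift, r.antecedent, r.consequent))
    return RuleBase(tuple(rules), thresholds, n)


def mine_rules(db: TransactionDB, thresholds: Thresholds = Thresholds()) -> RuleBase:
    """Convenience: mine frequent itemsets, then derive the rule base."""
    itemsets = mine_frequent_itemsets(db, thresholds.min_sup)
    return derive_rules(itemsets, db, thresholds)


RULE_CSV_COLUMNS = ["antecedent", "consequent", "support_count", "sup", "conf", "lift"]


def write_rules(rulebase: RuleBase, path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in RULE_CSV_COLUMNS}
                       for r in rulebase.rules], columns=RULE_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_rules(path: str | Path, thresholds: Thresholds = Thresholds(),
               n_transactions: int = 0) -> RuleBase:
    df = pd.read_csv(path, dtype={"antecedent": str, "consequent": str})
    rules = tuple(AssociationRule(r.antecedent, r.consequent, int(r.support_count),
                                  float(r.sup), float(r.conf), float(r.lift))
                  for r in df.itertuples(index=False))
    return RuleBase(rules, thresholds, n_transactions)
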