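"""External verification of mined rules against a local co-occurrence cache
and a literature annotation list.

The cache is a snapshot of COHD-style clinical co-occurrence data: for a
pair of concept keys it stores either a pre-computed chi-square p-value, a
2x2 co-occurrence table (n_both, n_a_only, n_b_only, n_neither), or both.
Concept keys are ICD-10 code strings truncated to three or four characters
(an OMOP concept-ID mapping is not required).

Because mined items rarely match cache keys exactly, matching is fuzzy:

* a dotted code tries its four-character prefix first, then its
  three-character category (F41.101 -> F41.1, then F41);
* a block label (L20-L30) is split back into the member raw codes observed
  in the data, each truncated the same way;
* a rule is *significant* if ANY candidate pair is found with p < 0.05.

Pearson's chi-square on the 2x2 table uses one degree of freedom and no
continuity correction; no multiple-testing adjustment is applied by default,
though a Bonferroni option is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._icd import is_block_label, is_valid_code
from .mining import AssociationRule

SIGNIFICANT = "significant"
NOT_SIGNIFICANT = "not_significant"
NOT_FOUND = "not_found"

CONFIRMED = "confirmed"
NOT_CONFIRMED = "not_confirmed"
NOT_CHECKED = "not_checked"

ALPHA = 0.05


class DegenerateTableError(ValueError):
    """A 2x2 table has a zero row or column marginal."""


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value for a 2x2 table (1 df,
    no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has a zero marginal")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


@dataclass(frozen=True)
class PairRecord:
    """Cache entry for one concept-key pair."""

    counts: tuple[int, int, int, int] | None = None  # n_both, n_a_only, n_b_only, n_neither
    p_value: float | None = None

    def p(self) -> float:
        """Stored p-value if present, else computed from the counts."""
        if self.p_value is not None:
            return self.p_value
        if self.counts is None:
            raise ValueError("pair record holds neither counts nor p-value")
        n_both, n_a, n_b, n_neither = self.counts
        _, p = chi_square_2x2([[n_both, n_a], [n_b, n_neither]])
        return p


@dataclass(frozen=True)
class CohdCache:
    """Symmetric pair-keyed co-occurrence snapshot."""

    pair_records: Mapping[frozenset[str], PairRecord]

    @property
    def known_keys(self) -> set[str]:
        out: set[str] = set()
        for pair in self.pair_records:
            out |= pair
        return out

    def lookup(self, key_a: str, key_b: str) -> PairRecord | None:
        return self.pair_records.get(frozenset((key_a, key_b)))


def load_cache(path: str | Path) -> CohdCache:
    """Read a code_a,code_b,n_both,n_a_only,n_b_only,n_neither[,p_value] CSV.

    When both counts and a p-value are present they must agree to 1e-6.
    """
    df = pd.read_csv(path, dtype={"code_a": str, "code_b": str})
    records: dict[frozenset[str], PairRecord] = {}
    count_cols = ["n_both", "n_a_only", "n_b_only", "n_neither"]
    for row in df.itertuples(index=False):
        counts = None
        if all(hasattr(row, c) and pd.notna(getattr(row, c)) for c in count_cols):
            counts = tuple(int(getattr(row, c)) for c in count_cols)
        p = None
        if hasattr(row, "p_value") and pd.notna(row.p_value):
            p = float(row.p_value)
        rec = PairRecord(counts=counts, p_value=p)
        if counts is not None and p is not None:
            recomputed = PairRecord(counts=counts).p()
            if abs(recomputed - p) > 1e-6:
                raise ValueError(f"stored p {p} disagrees with counts "
                                 f"(recomputed {recomputed}) for "
                                 f"({row.code_a}, {row.code_b})")
        records[frozenset((row.code_a, row.code_b))] = rec
    return CohdCache(records)


def builtin_cache_path() -> Path:
    """Path of the shipped synthetic co-occurrence snapshot.

    The snapshot is synthetic data covering the default code universe; it
    stands in for a real COHD download so the verification stage is runnable
    out of the box.
    """
    return Path(__file__).parent / "data" / "cohd_cache_synthetic.csv"


def _truncations(code: str) -> list[str]:
    """Four-character prefix first (if dotted), then the 3-char category."""
    if "." in code:
        return [code[:5], code[:3]]
    return [code]


def candidate_keys(item_label: str, cache: CohdCache,
                   block_members: Mapping[str, Iterable[str]] | None = None,
                   ) -> list[str]:
    """Ordered cache keys to try for a mined item, most specific first.

    ``block_members`` maps a level-2 block label to the raw codes observed
    under it in the study data; keys absent from the cache are dropped while
    preserving priority order.
    """
    if is_block_label(item_label):
        members = list((block_members or {}).get(item_label, ()))
        keys: list[str] = []
        for member in members:
            keys.extend(_truncations(member))
    elif is_valid_code(item_label):
        keys = _truncations(item_label)
    else:
        raise ValueError(f"unrecognized item label shape: {item_label!r}")
    known = cache.known_keys
    seen: set[str] = set()
    out = []
    for k in keys:
        if k in known and k not in seen:
            out.append(k)
            seen.add(k)
    return out


@dataclass(frozen=True)
class VerificationRecord:
    rule: AssociationRule
    cohd_status: str
    literature_status: str
    final_class: str


def _final_class(cohd_status: str, literature_status: str) -> str:
    cohd_yes = cohd_status == SIGNIFICANT
    lit_yes = literature_status == CONFIRMED
    if cohd_yes and lit_yes:
        return "cohd+literature"
    if cohd_yes:
        return "cohd_only"
    if lit_yes:
        return "literature_only"
    return "unverified"


def verify_rule(rule: AssociationRule, cache: CohdCache,
                literature: Mapping[tuple[str, str], bool] | None = None,
                block_members: Mapping[str, Iterable[str]] | None = None,
                alpha: float = ALPHA,
                bonferroni: bool = False) -> VerificationRecord:
    """Classify one rule against the cache and the literature list.

    The rule is COHD-significant if any candidate key pair is cached with
    p < alpha (alpha divided by the number of cached pairs tried when
    ``bonferroni`` is set).
    """
    keys_a = candidate_keys(rule.antecedent, cache, block_members)
    keys_b = candidate_keys(rule.consequent, cache, block_members)
    found_pairs = [rec for ka in keys_a for kb in keys_b
                   if (rec := cache.lookup(ka, kb)) is not None]
    if not found_pairs:
        cohd_status = NOT_FOUND
    else:
        threshold = alpha / len(found_pairs) if bonferroni else alpha
        cohd_status = (SIGNIFICANT if any(rec.p() < threshold for rec in found_pairs)
                       else NOT_SIGNIFICANT)
    if literature is None:
        literature_status = NOT_CHECKED
    else:
        flag = literature.get((rule.antecedent, rule.consequent))
        literature_status = (NOT_CHECKED if flag is None
                             else CONFIRMED if flag else NOT_CONFIRMED)
    return VerificationRecord(rule, cohd_status, literature_status,
                              _final_class(cohd_status, literature_status))


def verify_rules(rules: Iterable[AssociationRule], cache: CohdCache,
                 literature: Mapping[tuple[str, str], bool] | None = None,
                 block_members: Mapping[str, Iterable[str]] | None = None,
                 **kwargs) -> list[VerificationRecord]:
    return [verify_rule(r, cache, literature, block_members, **kwargs)
            for r in rules]


def tabulate_agreement(records: Sequence[VerificationRecord]) -> pd.DataFrame:
    """2x2 agreement table (literature yes/no x COHD yes/no) with margins."""
    counts = np.zeros((2, 2), dtype=int)
    for rec in records:
        i = 0 if rec.literature_status == CONFIRMED else 1
        j = 0 if rec.cohd_status == SIGNIFICANT else 1
        counts[i, j] += 1
    df = pd.DataFrame(counts,
                      index=pd.Index(["literature_yes", "literature_no"]),
                      columns=["cohd_yes", "cohd_no"])
    df["total"] = df.sum(axis=1)
    df.loc["total"] = df.sum(axis=0)
    return df


def load_literature(path: str | Path) -> dict[tuple[str, str], bool]:
    """Read an antecedent,consequent,confirmed annotation CSV."""
    df = pd.read_csv(path, dtype={"antecedent": str, "consequent": str})
    truthy = {"true", "1", "yes", "y"}
    return {(r.antecedent, r.consequent): str(r.confirmed).strip().lower() in truthy
            for r in df.itertuples(index=False)}


def write_annotated_rules(records: Sequence[VerificationRecord],
                          path: str | Path) -> None:
    rows = []
    for rec in records:
        r = rec.rule
        rows.append({"antecedent": r.antecedent, "consequent": r.consequent,
                     "support_count": r.support_count, "sup": r.sup,
                     "conf": r.conf, "lift": r.lift,
                     "cohd_status": rec.cohd_status,
                     "literature_status": rec.literature_status,
                     "final_class": rec.final_class})
    pd.DataFrame(rows).to_csv(path, index=False)
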