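"""Inclusion/exclusion filters, three-level code generalization, and the
per-patient transaction database.

Raw diagnosis codes are mapped to *items* at one of three levels:

* level 0 — the raw code is kept verbatim.  This applies to codes that are
  already three-character categories, to six-digit NOS/NEC subcategories
  (which encode clinical detail that must not be merged), to abnormal-finding
  codes R90-R94, and to F84.2-F84.9 (pervasive developmental disorders that
  are deliberately not merged with autism).
* level 1 — the code collapses to its three-character category; F84.0 and
  F84.1 both become the autism item "F84".
* level 2 — the category falls inside a configured chapter block
  (e.g. F70-F79) and the block label becomes the item.

Supplementary chapter codes (V01-Y98, Z00-Z99) are excluded before mapping,
and patients left with fewer than ``min_items`` items are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import _icd
from .records import DiagnosisRecord

#: Standard ICD-10 chapter blocks used for level-2 grouping.
DEFAULT_BLOCK_TABLE: tuple[tuple[str, str, str], ...] = (
    ("F70-F79", "F70", "F79"),
    ("G20-G26", "G20", "G26"),
    ("G40-G41", "G40", "G41"),
    ("G90-G99", "G90", "G99"),
    ("J00-J06", "J00", "J06"),
    ("J20-J22", "J20", "J22"),
    ("L20-L30", "L20", "L30"),
    ("E00-E07", "E00", "E07"),
)

#: Six-digit subcategory codes flagged NOS/NEC in the default universe.
DEFAULT_NOS_NEC_CODES: frozenset[str] = frozenset({
    "F41.001", "F41.101", "F82.x00", "G98.x00", "E58.x00", "E60.x00",
    "E22.802", "E34.300", "J00.x00", "V01.x00", "R94.001", "D64.901",
})

EXCLUDED_RANGES: tuple[tuple[str, str], ...] = (("V01", "Y98"), ("Z00", "Z99"))


class MappingConfigurationError(ValueError):
    """A raw code is covered by more than one block row."""


@dataclass(frozen=True)
class GeneralizationMap:
    """Total mapping raw code -> (level, item label)."""

    entries: Mapping[str, tuple[int, str]]
    block_table: tuple[tuple[str, str, str], ...] = DEFAULT_BLOCK_TABLE

    def item(self, code: str) -> str:
        if code in self.entries:
            return self.entries[code][1]
        # Item labels themselves map to themselves so the map is idempotent.
        if code in {label for _, label in self.entries.values()}:
            return code
        raise KeyError(f"code {code!r} not covered by the generalization map")

    def level(self, code: str) -> int:
        return self.entries[code][0]


def exclude_chapters(records: Sequence[DiagnosisRecord]) -> list[DiagnosisRecord]:
    """Drop records from the supplementary chapters V01-Y98 and Z00-Z99."""
    kept = []
    for rec in records:
        cat = _icd.category(rec.icd10_code)
        if any(_icd.in_range(cat, lo, hi) for lo, hi in EXCLUDED_RANGES):
            continue
        kept.append(rec)
    return kept


def build_generalization_map(
    observed_codes: Iterable[str],
    block_table: Sequence[tuple[str, str, str]] = DEFAULT_BLOCK_TABLE,
    level0_exceptions: Iterable[str] = DEFAULT_NOS_NEC_CODES,
    overrides: Mapping[str, tuple[int, str]] | None = None,
) -> GeneralizationMap:
    """Assign each observed raw code to its generalization level and item.

    ``level0_exceptions`` is the NOS/NEC flag list; ``overrides`` (raw code ->
    (level, label)) wins over the rule-derived assignment and lets users
    substitute an explicit mapping table.
    """
    level0 = frozenset(level0_exceptions)
    entries: dict[str, tuple[int, str]] = {}
    for code in sorted(set(observed_codes)):
        if overrides and code in overrides:
            entries[code] = overrides[code]
            continue
        cat = _icd.category(code)
        sub = code[4:] if len(code) > 3 else ""
        if len(code) == 3:
            entries[code] = (0, code)
        elif code in level0:
            entries[code] = (0, code)
        elif _icd.in_range(cat, "R90", "R94"):
            entries[code] = (0, code)
        elif cat == "F84" and sub[:1] in set("23456789"):
            entries[code] = (0, code)
        elif cat == "F84":
            entries[code] = (1, "F84")
        else:
            rows = [label for label, lo, hi in block_table if _icd.in_range(cat, lo, hi)]
            if len(rows) > 1:
                raise MappingConfigurationError(
                    f"code {code!r} matches multiple block rows: {rows}")
            if rows:
                entries[code] = (2, rows[0])
            else:
                entries[code] = (1, cat)
    return GeneralizationMap(entries=entries, block_table=tuple(block_table))


def load_mapping_overrides(path: str | Path) -> dict[str, tuple[int, str]]:
    """Read a raw_code,level,item_label CSV of explicit mapping overrides."""
    df = pd.read_csv(path, dtype={"raw_code": str, "level": int, "item_label": str})
    return {r.raw_code: (int(r.level), r.item_label) for r in df.itertuples(index=False)}


def load_block_table(path: str | Path) -> tuple[tuple[str, str, str], ...]:
    """Read a block_label,low,high CSV."""
    df = pd.read_csv(path, dtype=str)
    return tuple((r.block_label, r.low, r.high) for r in df.itertuples(index=False))


@dataclass(frozen=True)
class TransactionDB:
    """Per-patient sets of generalized items: the miner's input dataset."""

    transactions: Mapping[str, frozenset[str]]

    @property
    def n_patients(self) -> int:
        return len(self.transactions)

    @property
    def item_frequencies(self) -> dict[str, int]:
        freq: dict[str, int] = {}
        for items in self.transactions.values():
            for it in items:
                freq[it] = freq.get(it, 0) + 1
        return freq

    @property
    def items(self) -> set[str]:
        out: set[str] = set()
        for items in self.transactions.values():
            out |= items
        return out


def build_transactions(records: Sequence[DiagnosisRecord],
                       gmap: GeneralizationMap) -> TransactionDB:
    """Collapse each patient's visit-level codes into one generalized item set."""
    per_patient: dict[str, set[str]] = {}
    for rec in records:
        per_patient.setdefault(rec.patient_id, set()).add(gmap.item(rec.icd10_code))
    return TransactionDB({pid: frozenset(items) for pid, items in per_patient.items()})


def filter_patients(db: TransactionDB, min_items: int = 2) -> TransactionDB:
    """Keep patients with at least ``min_items`` distinct items.

    The default of 2 counts the autism anchor itself, i.e. a kept patient has
    the anchor plus at least one comorbid item.
    """
    return TransactionDB({pid: items for pid, items in db.transactions.items()
                          if len(items) >= min_items})


def summarize_cohort(records: Sequence[DiagnosisRecord],
                     db: TransactionDB) -> pd.DataFrame:
    """Demographic summary of the filtered cohort: counts and percentages for
    sex, age band at first visit, region, and visit-count bins.
    """
    from .synthetic import AGE_BANDS

    kept = set(db.transactions)
    by_patient: dict[str, list[DiagnosisRecord]] = {}
    for rec in records:
        if rec.patient_id in kept:
            by_patient.setdefault(rec.patient_id, []).append(rec)

    band_names = ["early childhood", "middle childhood",
                  "early adolescence", "late adolescence"]
    rows: list[tuple[str, str]] = []
    for pid, recs in by_patient.items():
        sex = recs[0].sex
        region = recs[0].region
        visit_ids = sorted({r.visit_id for r in recs})
        first_visit = visit_ids[0]
        first_age = min(r.age_years for r in recs if r.visit_id == first_visit)
        band = next(name for name, (lo, hi) in zip(band_names, AGE_BANDS)
                    if lo <= first_age <= hi)
        n_visits = len(visit_ids)
        vbin = "1-9" if n_visits <= 9 else ("10-19" if n_visits <= 19 else "20+")
        rows.append((sex, band, region, vbin))

    df = pd.DataFrame(rows, columns=["sex", "age_band", "region", "visit_bin"])
    n = len(df)
    out = []
    for characteristic, order in [
        ("sex", ["male", "female"]),
        ("age_band", band_names),
        ("region", ["urban", "rural"]),
        ("visit_bin", ["1-9", "10-19", "20+"]),
    ]:
        counts = df[characteristic].value_counts()
        for value in order:
            c = int(counts.get(value, 0))
            out.append({"characteristic": characteristic, "value": value,
                        "count": c, "percent": round(100.0 * c / n, 2) if n else 0.0})
    return pd.DataFrame(out)
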