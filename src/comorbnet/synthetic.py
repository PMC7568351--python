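"""Synthetic diagnosis cohorts with planted comorbidity structure.

The generator emulates a pediatric autism cohort: every patient carries the
anchor autism code (F84.0 if first seen before age 3, F84.1 otherwise), a
long-tailed set of comorbid codes drawn independently per patient, and a
configurable list of *planted* pairs (X, Y, p) realized as
P(Y present | X present) = p, so that the design support, confidence and
lift of each planted rule are known exactly.  Codes are scattered across a
patient's visits, with occasional repeats, to exercise downstream
multi-visit deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._icd import is_valid_code
from .records import DiagnosisRecord

# Age bands (inclusive year ranges): early childhood, middle childhood,
# early adolescence, late adolescence.
AGE_BANDS: tuple[tuple[int, int], ...] = ((0, 4), (5, 9), (10, 14), (15, 18))

# Visit-count bins and the within-bin integer ranges they cover.
VISIT_BINS: tuple[tuple[int, int], ...] = ((1, 9), (10, 19), (20, 30))

#: Long-tailed default code universe: (code, base prevalence).  Mirrors the
#: headline comorbidity categories of a pediatric autism cohort — intellectual
#: disability (F70-F79 members), speech disorder (F80), epilepsy (G40-G41),
#: ADHD (F90), convulsions (R56), nutrient deficiencies (E58/E60/E61), acute
#: upper respiratory infections (J00-J06 members) — plus V/Z decoy codes that
#: the chapter-exclusion step must remove.
DEFAULT_CODE_UNIVERSE: tuple[tuple[str, float], ...] = (
    ("F70.900", 0.30), ("F71.900", 0.12), ("F78.100", 0.05), ("F79.100", 0.08),
    ("F80.000", 0.28), ("F80.100", 0.10), ("F90.000", 0.18), ("F95.100", 0.06),
    ("F82.x00", 0.07), ("F98.800", 0.04), ("F41.001", 0.015), ("F41.101", 0.012),
    ("G40.900", 0.14), ("G41.900", 0.03), ("G47.900", 0.05), ("G25.300", 0.02),
    ("G93.400", 0.025), ("G98.x00", 0.015),
    ("R56.000", 0.20), ("R62.000", 0.15), ("R62.800", 0.05), ("R94.001", 0.06),
    ("R90.800", 0.015), ("R50.900", 0.04), ("R10.400", 0.02),
    ("E58.x00", 0.10), ("E61.100", 0.06), ("E60.x00", 0.05), ("E22.802", 0.02),
    ("E03.900", 0.015), ("E34.300", 0.02),
    ("J00.x00", 0.08), ("J02.900", 0.05), ("J03.900", 0.04), ("J06.900", 0.06),
    ("J20.900", 0.03), ("J32.900", 0.012),
    ("L20.800", 0.025), ("L30.900", 0.02), ("D64.901", 0.015),
    ("K59.000", 0.02), ("H52.200", 0.01),
    ("Z00.000", 0.08), ("V01.x00", 0.005),
)

#: Planted directed comorbidity pairs (antecedent, consequent, conditional
#: probability): nutrient-deficiency chain and the epilepsy/convulsions link.
DEFAULT_PLANTED_PAIRS: tuple[tuple[str, str, float], ...] = (
    ("E58.x00", "E61.100", 0.60),
    ("E58.x00", "E60.x00", 0.45),
    ("G40.900", "R56.000", 0.70),
    ("F70.900", "F80.000", 0.55),
)


class ConfigurationError(ValueError):
    """The cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic cohort.

    Defaults reproduce the study conditions of the cohort being emulated:
    1488 patients, 82.66% male, first-visit age bands 59.88/34.34/5.58/0.20%,
    visit-count bins 96.24/2.55/1.21%, 81.76% urban.
    """

    n_patients: int = 1488
    code_universe: Sequence[tuple[str, float]] = DEFAULT_CODE_UNIVERSE
    planted_pairs: Sequence[tuple[str, str, float]] = DEFAULT_PLANTED_PAIRS
    anchor_codes: tuple[str, str] = ("F84.0", "F84.1")
    male_fraction: float = 0.8266
    age_band_weights: Sequence[float] = (0.5988, 0.3434, 0.0558, 0.0020)
    visit_count_weights: Sequence[float] = (0.9624, 0.0255, 0.0121)
    urban_fraction: float = 0.8176
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        codes = {c for c, _ in self.code_universe}
        for code, prev in self.code_universe:
            if not is_valid_code(code):
                raise ConfigurationError(f"invalid code in universe: {code!r}")
            if not 0 < prev <= 1:
                raise ConfigurationError(f"prevalence of {code} not in (0,1]: {prev}")
        for a, b, p in self.planted_pairs:
            if a not in codes or b not in codes:
                raise ConfigurationError(f"planted pair ({a},{b}) not in code universe")
            if not 0 < p <= 1:
                raise ConfigurationError(f"planted probability not in (0,1]: {p}")
        for frac, name in ((self.male_fraction, "male_fraction"),
                           (self.urban_fraction, "urban_fraction")):
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"{name} not in [0,1]: {frac}")
        for w, n_expected, name in ((self.age_band_weights, 4, "age_band_weights"),
                                    (self.visit_count_weights, 3, "visit_count_weights")):
            if len(w) != n_expected or any(x < 0 for x in w) or sum(w) <= 0:
                raise ConfigurationError(f"{name} must be {n_expected} non-negative "
                                         "weights with positive sum")

    @property
    def prevalence(self) -> dict[str, float]:
        return dict(self.code_universe)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> list[DiagnosisRecord]:
    """Draw a full synthetic cohort; deterministic given config and seed.

    Per patient: the anchor code is always present; non-planted codes are
    independent Bernoulli(prevalence); for each planted pair (X, Y, p) the
    consequent's indicator is re-drawn as Bernoulli(p) whenever X is present.
    The patient's code set is then distributed over its visits uniformly at
    random, with each code given a 30% chance of a repeat at a second visit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    codes = [c for c, _ in config.code_universe]
    prevs = np.array([p for _, p in config.code_universe])
    planted_idx = [(codes.index(a), codes.index(b), p) for a, b, p in config.planted_pairs]

    records: list[DiagnosisRecord] = []
    n_digits = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{n_digits}d}"
        sex = "male" if rng.random() < config.male_fraction else "female"
        region = "urban" if rng.random() < config.urban_fraction else "rural"
        band = rng.choice(len(AGE_BANDS), p=np.asarray(config.age_band_weights)
                          / np.sum(config.age_band_weights))
        lo, hi = AGE_BANDS[band]
        first_age = int(rng.integers(lo, hi + 1))
        anchor = config.anchor_codes[0] if first_age < 3 else config.anchor_codes[1]

        present = rng.random(len(codes)) < prevs
        for ai, bi, p in planted_idx:
            if present[ai]:
                present[bi] = rng.random() < p
        patient_codes = [anchor] + [c for c, keep in zip(codes, present) if keep]

        vbin = rng.choice(len(VISIT_BINS), p=np.asarray(config.visit_count_weights)
                          / np.sum(config.visit_count_weights))
        vlo, vhi = VISIT_BINS[vbin]
        n_visits = int(rng.integers(vlo, vhi + 1))
        # visits occur within a 3-year study window
        visit_ages = np.minimum(first_age + np.sort(rng.integers(0, 3, size=n_visits)), 18)
        visit_ages[0] = first_age

        for code in patient_codes:
            visits = {int(rng.integers(0, n_visits))}
            if n_visits > 1 and rng.random() < 0.30:
                visits.add(int(rng.integers(0, n_visits)))
            for v in sorted(visits):
                records.append(DiagnosisRecord(
                    patient_id=pid,
                    visit_id=f"{pid}-V{v + 1:02d}",
                    icd10_code=code,
                    sex=sex,
                    age_years=int(visit_ages[v]),
                    region=region,
                ))
    return records


@dataclass(frozen=True)
class PlantedRule:
    """A designed directed association with its generative parameters."""

    antecedent: str
    consequent: str
    design_conf: float
    design_lift: float


def planted_truth(config: CohortConfig) -> list[PlantedRule]:
    """The planted directed pairs with their design confidence and lift.

    Design lift is the conditional probability divided by the consequent's
    base prevalence.  (The realized marginal of the consequent is slightly
    inflated, prev_B + prev_A * (p - prev_B), so empirical lift estimates sit
    a little below this design value; recovery tests compare confidence, which
    is unaffected.)
    """
    config.validate()
    prev = config.prevalence
    return [PlantedRule(a, b, design_conf=p, design_lift=p / prev[b])
            for a, b, p in config.planted_pairs]
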