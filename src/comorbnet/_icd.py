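"""ICD-10 code shapes, ordering, and chapter classification.

An ICD-10 code is a three-character category (letter + two digits, e.g.
``F84``) optionally followed by a dot and one to three further alphanumeric
characters (``F84.0``, ``F70.900``, ``E58.x00``).  Categories are fixed-width
alphanumerics, so lexicographic comparison of the three-character category
coincides with ontological order; all range tests below rely on that.
"""

from __future__ import annotations

import re

CODE_PATTERN = re.compile(r"^[A-Z]\d{2}(\.[A-Za-z0-9]{1,3})?$")

#: Block label of form "Xnn-Xmm" (e.g. "F70-F79"), used for level-2 items.
BLOCK_LABEL_PATTERN = re.compile(r"^([A-Z]\d{2})-([A-Z]\d{2})$")

# ICD-10 chapters as (number, low category, high category).  S00-T98 and
# similar split-letter chapters are encoded by their full category span.
CHAPTERS: list[tuple[str, str, str]] = [
    ("I", "A00", "B99"),
    ("II", "C00", "D48"),
    ("III", "D50", "D89"),
    ("IV", "E00", "E90"),
    ("V", "F00", "F99"),
    ("VI", "G00", "G99"),
    ("VII", "H00", "H59"),
    ("VIII", "H60", "H95"),
    ("IX", "I00", "I99"),
    ("X", "J00", "J99"),
    ("XI", "K00", "K93"),
    ("XII", "L00", "L99"),
    ("XIII", "M00", "M99"),
    ("XIV", "N00", "N99"),
    ("XV", "O00", "O99"),
    ("XVI", "P00", "P96"),
    ("XVII", "Q00", "Q99"),
    ("XVIII", "R00", "R99"),
    ("XIX", "S00", "T98"),
    ("XX", "V01", "Y98"),
    ("XXI", "Z00", "Z99"),
    ("XXII", "U00", "U99"),
]


def is_valid_code(code: str) -> bool:
    return bool(CODE_PATTERN.match(code))


def category(code: str) -> str:
    """Three-character category of a raw code ("F84.0" -> "F84")."""
    return code[:3]


def in_range(cat: str, low: str, high: str) -> bool:
    """Lexicographic range test on three-character categories."""
    return low <= cat <= high


def is_block_label(label: str) -> bool:
    m = BLOCK_LABEL_PATTERN.match(label)
    return bool(m) and m.group(1) <= m.group(2)


def chapter_of(item_label: str) -> str:
    """ICD-10 chapter number for a raw code, category, or block label.

    Block labels are classified by their low endpoint.
    """
    if is_block_label(item_label):
        cat = item_label[:3]
    else:
        cat = category(item_label)
    for number, low, high in CHAPTERS:
        if in_range(cat, low, high):
            return number
    raise ValueError(f"no ICD-10 chapter covers category {cat!r}")
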