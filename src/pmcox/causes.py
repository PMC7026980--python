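"""ICD-10 cause-of-death grouping.

Causes of death are defined as inclusive ranges of ICD-10 *category roots*
(a letter plus two digits, e.g. ``I21``); any subcode (``I21.4``) inherits
the mapping of its root. Range membership is lexicographic on the root,
which is the standard ICD-10 ordering within and across letter blocks.

The default map implements the conventional elderly-mortality hierarchy:
non-accidental (A00–R99) vs accidental (V01–Y98), cardiovascular I00–I99
with ischemic heart disease (IHD) I20–I25, cerebrovascular (CBV) I60–I69
and congestive heart failure (CHF) I50; respiratory J00–J99 with COPD
J40–J44 and pneumonia J12–J18; neoplasms C00–D48 with lung cancer C34.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\.?([0-9A-Z]{1,4}))?$")

#: name -> list of "X00-Y99" (or single-root "C34") range strings
DEFAULT_CAUSE_RANGES: dict[str, list[str]] = {
    "all_cause": ["A00-Y98"],
    "non_accidental": ["A00-R99"],
    "accidental": ["V01-Y98"],
    "all_cvd": ["I00-I99"],
    "ihd": ["I20-I25"],
    "cbv": ["I60-I69"],
    "chf": ["I50-I50"],
    "all_respiratory": ["J00-J99"],
    "copd": ["J40-J44"],
    "pneumonia": ["J12-J18"],
    "all_cancer": ["C00-D48"],
    "lung_cancer": ["C34-C34"],
}

#: subset relations that must hold for any well-formed cause map
HIERARCHY: list[tuple[str, str]] = [
    ("ihd", "all_cvd"),
    ("cbv", "all_cvd"),
    ("chf", "all_cvd"),
    ("copd", "all_respiratory"),
    ("pneumonia", "all_respiratory"),
    ("lung_cancer", "all_cancer"),
]


class ICDParseError(ValueError):
    """Raised for strings that are not syntactically valid ICD-10 codes."""


def icd_root(code: str) -> str:
    """Return the three-character category root of an ICD-10 code.

    >>> icd_root("I21.4")
    'I21'
    """
    m = _CODE_RE.match(str(code).strip().upper())
    if not m:
        raise ICDParseError(f"malformed ICD-10 code: {code!r}")
    return m.group(1) + m.group(2)


def _parse_range(spec: str) -> tuple[str, str]:
    parts = spec.strip().upper().split("-")
    if len(parts) == 1:
        lo = hi = icd_root(parts[0])
    elif len(parts) == 2:
        lo, hi = icd_root(parts[0]), icd_root(parts[1])
    else:
        raise ValueError(f"bad ICD range spec: {spec!r}")
    if lo > hi:
        raise ValueError(f"inverted ICD range: {spec!r}")
    return lo, hi


@dataclass
class CauseOfDeathMap:
    """Named causes of death, each an inclusive set of ICD-10 root ranges."""

    ranges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CauseOfDeathMap":
        return cls.from_ranges(DEFAULT_CAUSE_RANGES)

    @classmethod
    def from_ranges(cls, spec: dict[str, list[str]]) -> "CauseOfDeathMap":
        return cls({name: [_parse_range(r) for r in rs] for name, rs in spec.items()})

    @property
    def causes(self) -> list[str]:
        return list(self.ranges)

    def contains(self, cause: str, code: str) -> bool:
        root = icd_root(code)
        return any(lo <= root <= hi for lo, hi in self.ranges[cause])

    def classify(self, code: str) -> set[str]:
        """Every cause whose range contains the code's three-character root."""
        root = icd_root(code)
        return {
            name
            for name, rs in self.ranges.items()
            if any(lo <= root <= hi for lo, hi in rs)
        }

    def roots_in(self, cause: str) -> list[str]:
        """All syntactically possible roots inside a cause's ranges (for sampling)."""
        out = []
        for lo, hi in self.ranges[cause]:
            for letter in (chr(c) for c in range(ord(lo[0]), ord(hi[0]) + 1)):
                d0 = int(lo[1:]) if letter == lo[0] else 0
                d1 = int(hi[1:]) if letter == hi[0] else 99
                out.extend(f"{letter}{d:02d}" for d in range(d0, d1 + 1))
        return out


def classify_cause(code: str, cause_map: CauseOfDeathMap | None = None) -> set[str]:
    """Map an ICD-10 code to the set of cause labels whose ranges contain it."""
    return (cause_map or CauseOfDeathMap.default()).classify(code)
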