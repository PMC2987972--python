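"""ICD-9-CM code handling.

Claims carry ICD-9-CM diagnosis codes at "level 5", the most detailed recorded
form: 3-5 characters once the decimal point is removed (e.g. ``4019``, ``73390``,
``V700``, ``E8490``).  The canonical in-package form is dot-free and upper-case;
code lists written the human way (``714.0*``) are handled by
:class:`Icd9Pattern`.

The screen excludes diagnosis chapters that are part of, or trivially secondary
to, the index condition of a rheumatoid-arthritis-style study: arthropathies and
related disorders (stems 710-719), dorsopathies (720-724), rheumatism excluding
the back (725-729), and mechanical complication of an internal orthopedic
device/implant/graft (996.4).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import Icd9Error

__all__ = ["normalize_icd9", "Icd9Pattern", "matches", "is_excluded_code"]

# First character may be a letter (V/E supplemental chapters), the rest digits;
# 3-5 characters total after dot removal.
_CODE_RE = re.compile(r"[A-Z0-9][0-9]{2,4}")

EXCLUDED_STEM_RANGE = (710, 729)
EXCLUDED_PREFIX = "9964"


def normalize_icd9(raw: str) -> str:
    """Normalize a raw ICD-9 code string to canonical dot-free upper-case form.

    Idempotent: ``normalize_icd9(normalize_icd9(x)) == normalize_icd9(x)``.

    Raises
    ------
    Icd9Error
        If the input is empty or, after stripping whitespace and the decimal
        point, does not consist of 3-5 characters (optionally one leading
        letter, then digits).
    """
    if raw is None:
        raise Icd9Error("ICD-9 code is missing (None)")
    text = str(raw).strip().upper()
    if text.count(".") > 1:
        raise Icd9Error(f"malformed ICD-9 code: {raw!r} (multiple dots)")
    code = text.replace(".", "")
    if not code:
        raise Icd9Error(f"ICD-9 code is empty: {raw!r}")
    if not _CODE_RE.fullmatch(code):
        raise Icd9Error(f"malformed ICD-9 code: {raw!r} (normalized form {code!r})")
    return code


@dataclass(frozen=True)
class Icd9Pattern:
    """A code pattern such as ``"714.0*"`` (prefix match) or ``"6960"`` (exact).

    A trailing ``*`` makes the pattern match every code starting with the
    normalized prefix; without it the pattern matches exactly one code.
    """

    pattern: str
    wildcard: bool = field(init=False)
    prefix: str = field(init=False)

    def __post_init__(self) -> None:
        raw = self.pattern.strip()
        wildcard = raw.endswith("*")
        stem = raw[:-1] if wildcard else raw
        object.__setattr__(self, "wildcard", wildcard)
        object.__setattr__(self, "prefix", normalize_icd9(stem))

    def match(self, code: str) -> bool:
        if self.wildcard:
            return code.startswith(self.prefix)
        return code == self.prefix


def matches(code: str, pattern: "Icd9Pattern | str") -> bool:
    """True iff normalized *code* matches *pattern* (exact, or prefix if it
    ends in ``*``)."""
    if not isinstance(pattern, Icd9Pattern):
        pattern = Icd9Pattern(pattern)
    return pattern.match(code)


def is_excluded_code(code: str) -> bool:
    """True for codes dropped from the comorbidity screen as index-condition
    related: 3-digit stem in 710-729, or any 996.4x code."""
    stem = code[:3]
    if stem.isdigit() and EXCLUDED_STEM_RANGE[0] <= int(stem) <= EXCLUDED_STEM_RANGE[1]:
        return True
    return code.startswith(EXCLUDED_PREFIX)
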