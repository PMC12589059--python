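"""WHO Anatomical Therapeutic Chemical (ATC) code handling.

ATC codes are hierarchical, seven characters at full depth:

=====  =======  ==============================  ========
level  chars    meaning                         example
=====  =======  ==============================  ========
1      1 (A-Z)  anatomical main group           ``N``
2      2 (0-9)  therapeutic subgroup            ``N05``
3      1 (A-Z)  pharmacological subgroup        ``N05C``
4      1 (A-Z)  chemical subgroup               ``N05CB``
5      2 (0-9)  chemical substance              ``N05CB01``
=====  =======  ==============================  ========

A truncated code at any of the legal lengths {1, 3, 4, 5, 7} is itself a
valid code and denotes the subtree rooted at that prefix.  Cluster labeling
works on level-1 prefixes; target identification works on level-4 prefixes.
"""

from __future__ import annotations

import re

from .errors import ParameterError

__all__ = ["LEVEL_LENGTHS", "validate_atc", "normalize_atc", "atc_prefix", "atc_level"]

#: Prefix length of each ATC level.
LEVEL_LENGTHS: dict[int, int] = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

_LENGTH_TO_LEVEL = {v: k for k, v in LEVEL_LENGTHS.items()}

# Positional character classes of a full 7-char code; a valid truncation
# must match the corresponding prefix of this pattern.
_ATC_RE = re.compile(r"^[A-Z]($|\d{2}($|[A-Z]($|[A-Z]($|\d{2}$))))")


def validate_atc(code: str) -> bool:
    """Return True iff *code* is a syntactically valid (possibly truncated) ATC code.

    Total function: never raises.  Matching is case-sensitive on the
    normalized (uppercase) form; use :func:`normalize_atc` on raw input.
    """
    if not isinstance(code, str) or len(code) not in _LENGTH_TO_LEVEL:
        return False
    return _ATC_RE.match(code) is not None


def normalize_atc(code: str) -> str:
    """Uppercase and strip *code*; raise if the result is not a valid ATC code."""
    norm = code.strip().upper()
    if not validate_atc(norm):
        raise ParameterError(f"not a valid ATC code: {code!r}")
    return norm


def atc_level(code: str) -> int:
    """The deepest level a valid code carries (1..5), from its length."""
    if not validate_atc(code):
        raise ParameterError(f"not a valid ATC code: {code!r}")
    return _LENGTH_TO_LEVEL[len(code)]


def atc_prefix(code: str, level: int) -> str:
    """Truncate a valid ATC *code* to the prefix that names its *level* group.

    ``atc_prefix("N05CB", 1) == "N"``; idempotent at the code's own level.
    Raises :class:`ParameterError` for an invalid level or a code that does
    not carry the requested level.
    """
    if level not in LEVEL_LENGTHS:
        raise ParameterError(f"ATC level must be in 1..5, got {level!r}")
    if not validate_atc(code):
        raise ParameterError(f"not a valid ATC code: {code!r}")
    length = LEVEL_LENGTHS[level]
    if len(code) < length:
        raise ParameterError(
            f"code {code!r} carries only level {_LENGTH_TO_LEVEL[len(code)]}, "
            f"cannot extract level {level}"
        )
    return code[:length]
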