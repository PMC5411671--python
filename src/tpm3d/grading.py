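"""Gleason pattern and score helpers.

A Gleason *pattern* (grade) is an architectural grade in {3, 4, 5}.  A Gleason
*score* is an ordered pair primary+secondary, e.g. ``(3, 4)`` printed "3+4".
Scores are ordered clinically by total first and then by primary pattern, so
that 3+3 < 3+4 < 4+3 < 3+5 < 4+4 < ...; this is the ordering used for risk
stratification and for picking a lesion's "best" score.
"""

from __future__ import annotations

from typing import Iterable

__all__ = [
    "PATTERNS",
    "GleasonPair",
    "validate_pattern",
    "validate_pair",
    "pair_rank",
    "pair_str",
    "parse_pair",
    "best_pair",
    "pair_total",
]

PATTERNS = (3, 4, 5)

GleasonPair = tuple[int, int]


def validate_pattern(p: int) -> int:
    if p not in PATTERNS:
        raise ValueError(f"Gleason pattern must be one of {PATTERNS}, got {p!r}")
    return int(p)


def validate_pair(pair: GleasonPair) -> GleasonPair:
    primary, secondary = pair
    return (validate_pattern(primary), validate_pattern(secondary))


def pair_total(pair: GleasonPair) -> int:
    return pair[0] + pair[1]


def pair_rank(pair: GleasonPair) -> tuple[int, int]:
    """Sort key implementing the clinical ordering (total, then primary)."""
    return (pair[0] + pair[1], pair[0])


def pair_str(pair: GleasonPair) -> str:
    return f"{pair[0]}+{pair[1]}"


def parse_pair(text: str) -> GleasonPair:
    try:
        primary, secondary = text.split("+")
        return validate_pair((int(primary), int(secondary)))
    except ValueError as exc:
        raise ValueError(f"cannot parse Gleason score {text!r}") from exc


def best_pair(pairs: Iterable[GleasonPair]) -> GleasonPair:
    """Highest score among ``pairs`` under the clinical ordering."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no Gleason scores given")
    return max(pairs, key=pair_rank)
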