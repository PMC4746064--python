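"""Shared helpers: taxon-label normalization and EC-number validation."""

from __future__ import annotations

import re

# Supported ranks, most specific first.
RANKS: tuple[str, ...] = ("genus", "family", "order", "class", "phylum")

# Greengenes/SILVA-style single-letter rank prefixes.
_PREFIX_TO_RANK = {
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
}
# Prefixes we recognise but do not resolve at (outside the five ranks).
_IGNORED_PREFIXES = {"k", "d", "s"}

_PREFIX_RE = re.compile(r"^([a-zA-Z])__")
_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")
_WS_RE = re.compile(r"\s+")


def split_rank_prefix(component: str) -> tuple[str | None, str]:
    """Split 'g__Streptococcus' into ('genus', 'Streptococcus').

    Returns (None, text) when there is no recognisable prefix; the rank is
    also None for prefixes outside the five supported ranks (kingdom,
    species), whose bare name is still returned.
    """
    component = component.strip()
    m = _PREFIX_RE.match(component)
    if m is None:
        return None, component
    letter = m.group(1).lower()
    rest = component[m.end():]
    if letter in _PREFIX_TO_RANK:
        return _PREFIX_TO_RANK[letter], rest
    return None, rest


def normalize_label(name: str) -> str:
    """Canonical comparison form: trimmed, whitespace-collapsed, prefix-free,
    case-insensitive."""
    _, bare = split_rank_prefix(name)
    return _WS_RE.sub(" ", bare.strip()).lower()


def is_valid_ec(ec: str) -> bool:
    """EC numbers are four dot-separated fields; '-' wildcards are allowed
    only in trailing positions (1.1.-.- yes, 1.-.1.1 no)."""
    if not _EC_RE.match(ec):
        return False
    fields = ec.split(".")
    seen_dash = False
    for f in fields:
        if f == "-":
            seen_dash = True
        elif seen_dash:
            return False
    return True


def is_wildcard_ec(ec: str) -> bool:
    return "-" in ec
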