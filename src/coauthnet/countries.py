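"""ISO-3166 country lookup and Africa region membership.

The country table and the alias table (common non-ISO spellings such as
"USA", "UK", "Tanzania") are shipped as editable plain-text package data,
so that region assignment is stable and auditable rather than tied to
whatever region taxonomy a third-party dependency happens to ship.
"""

from __future__ import annotations

import re
import string
from functools import lru_cache
from importlib import resources

#: Marker used wherever a country could not be resolved to an ISO code.
UNRESOLVED = "??"

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def normalize_token(text: str) -> str:
    """Case-fold, strip punctuation and collapse whitespace."""
    return re.sub(r"\s+", " ", text.casefold().translate(_PUNCT_TABLE)).strip()


def _read_tsv(name: str) -> list[list[str]]:
    raw = resources.files("coauthnet.data").joinpath(name).read_text(encoding="utf-8")
    lines = [ln for ln in raw.splitlines() if ln.strip()]
    return [ln.split("\t") for ln in lines[1:]]  # skip header


@lru_cache(maxsize=1)
def country_table() -> dict[str, dict]:
    """alpha-2 code -> {"name": str, "african": bool}."""
    return {
        code: {"name": name, "african": flag == "1"}
        for code, name, flag in _read_tsv("iso3166.tsv")
    }


@lru_cache(maxsize=1)
def name_to_code() -> dict[str, str]:
    """Normalized country name or alias -> alpha-2 code."""
    table = {normalize_token(row["name"]): code for code, row in country_table().items()}
    for alias, code in _read_tsv("country_aliases.tsv"):
        table[normalize_token(alias)] = code
    return table


def is_african(code: str) -> bool:
    """True if the ISO alpha-2 code belongs to the Africa region."""
    row = country_table().get(code)
    return bool(row and row["african"])


def country_name(code: str) -> str:
    return country_table()[code]["name"]


def african_codes() -> frozenset[str]:
    return frozenset(c for c, row in country_table().items() if row["african"])


def match_country_token(token: str) -> str:
    """Match one comma-separated address token against the country table.

    Address tokens often carry postal codes or state abbreviations before the
    country ("15213 PA United States of America"), so the longest word suffix
    of the token that names a country wins.
    """
    if token.strip() in country_table():  # bare alpha-2 code, case-sensitive
        return token.strip()
    norm = normalize_token(token)
    if not norm:
        return UNRESOLVED
    words = norm.split(" ")
    lookup = name_to_code()
    for k in range(min(len(words), 6), 0, -1):
        suffix = " ".join(words[-k:])
        if suffix in lookup:
            return lookup[suffix]
    return UNRESOLVED
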