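"""Entity resolution: countries, canonical institutions, regions, sectors.

Affiliation addresses are noisy free text ("Univ Cape Town, Cape Town,
South Africa"). Resolution proceeds in three passes:

1. country: the terminal comma-separated token of the address is matched
   against the ISO-3166 table (scanning backward), so an African country
   named mid-address never misclassifies a non-African affiliation;
2. institution: the leading substring before the first comma is clustered
   with single-linkage over a normalized edit similarity, merging database
   truncations and campus/department suffixes of the same institution;
3. sector: an ordered keyword rule list assigns one of eight operation
   sectors, with a manual override map that always wins.

Manual-review steps of a curated analysis are represented as override
files (variant -> canonical, name -> sector); overrides are authoritative
and applied after all automatic steps.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from . import countries
from .countries import UNRESOLVED, normalize_token
from .errors import ConfigurationError
from .records import Corpus

SECTORS = (
    "university",
    "hospital",
    "government",
    "intergovernmental",
    "research_institute",
    "private",
    "nonprofit",
    "research_network",
    "unknown",
)

#: Heuristic keyword scheme (regex on the normalized name, first match wins)
#: reconstructing an eight-sector coding of institution names. This rule set
#: is a keyword reconstruction, not an authoritative registry; curated
#: analyses refine it through the sector override file.
DEFAULT_SECTOR_RULES: tuple[tuple[str, str], ...] = (
    (r"\bcochrane\b", "research_network"),
    (r"\bcampbell collaborat", "research_network"),
    (r"\bnetwork\b", "research_network"),
    (r"\bconsortium\b", "research_network"),
    (r"\bwho\b", "intergovernmental"),
    (r"\bworld health org", "intergovernmental"),
    (r"\bunited nations\b", "intergovernmental"),
    (r"\bunicef\b", "intergovernmental"),
    (r"\bworld bank\b", "intergovernmental"),
    (r"\bafrican union\b", "intergovernmental"),
    (r"\buniv", "university"),
    (r"\bcollege\b", "university"),
    (r"\bpolytech", "university"),
    (r"\bhosp", "hospital"),
    (r"\bclin(ic|iq)", "hospital"),
    (r"\bmed(ical)? (ctr|cent)", "hospital"),
    (r"\bminist", "government"),
    (r"\bgov(t|ernment)\b", "government"),
    (r"\bdep(t|artment) of health\b", "government"),
    (r"\b(natl |national )?(agcy|agency)\b", "government"),
    (r"\binst", "research_institute"),
    (r"\bresearch council\b", "research_institute"),
    (r"\b(ctr|cent(er|re))\b", "research_institute"),
    (r"\blab(oratory)?\b", "research_institute"),
    (r"\b(ltd|inc|llc|gmbh|plc|pvt)\b", "private"),
    (r"pharma", "private"),
    (r"\b(foundation|fdn|ngo|trust|charity|society|assoc)", "nonprofit"),
)


@dataclass
class Institution:
    """Canonical institution entity with region and sector attributes."""

    canonical_id: str
    canonical_name: str
    country: str  # ISO alpha-2 or UNRESOLVED
    is_african: bool
    sector: str
    first_pub_year: int
    active_years: set[int] = field(default_factory=set)

    def __post_init__(self):
        if self.sector not in SECTORS:
            raise ValueError(f"unknown sector {self.sector!r}")


@dataclass
class NameClusterMap:
    """Variant -> canonical institution mapping produced by name clustering."""

    mapping: dict[str, str] = field(default_factory=dict)  # variant -> canonical_id
    canonical_names: dict[str, str] = field(default_factory=dict)  # id -> display name
    scores: dict[str, float] = field(default_factory=dict)  # variant -> merge score
    manual: set[str] = field(default_factory=set)  # variants set by override

    def canonical_of(self, variant: str) -> str:
        return self.mapping[variant]

    def clusters(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for variant, cid in self.mapping.items():
            out.setdefault(cid, set()).add(variant)
        return out

    def write_report(self, path: str | Path) -> None:
        """CSV audit trail: every variant with its canonical name and score."""
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["variant", "canonical_id", "canonical_name", "score", "manual"])
            for variant in sorted(self.mapping):
                cid = self.mapping[variant]
                writer.writerow(
                    [
                        variant,
                        cid,
                        self.canonical_names[cid],
                        f"{self.scores.get(variant, 1.0):.4f}",
                        int(variant in self.manual),
                    ]
                )


def parse_country(raw_text: str, alias_table: Mapping[str, str] | None = None) -> str:
    """Resolve the country of one address string.

    Comma-separated tokens are scanned from the end of the address backward
    until one matches the ISO-3166 table (or ``alias_table``, checked first).
    Returns the alpha-2 code, or the unresolved marker when nothing matches.
    """
    if not raw_text or not raw_text.strip():
        return UNRESOLVED
    tokens = [t for t in raw_text.split(",") if t.strip()]
    for token in reversed(tokens):
        if alias_table:
            norm = normalize_token(token)
            if norm in alias_table:
                return alias_table[norm]
        code = countries.match_country_token(token)
        if code != UNRESOLVED:
            return code
    return UNRESOLVED


def name_similarity(a: str, b: str) -> float:
    """Normalized edit similarity with a token-prefix containment bonus.

    Operates on pre-normalized names. A name whose token sequence is a
    prefix of the other's (a database truncation or a trailing campus/
    department qualifier) scores 1.0; otherwise 1 - d/max(|a|,|b|) with d
    the Levenshtein distance.
    """
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    ta, tb = a.split(" "), b.split(" ")
    if len(ta) != len(tb):
        short, long = (ta, tb) if len(ta) < len(tb) else (tb, ta)
        if long[: len(short)] == short:
            return 1.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _canonical_slug(name: str) -> str:
    return re.sub(r"\s+", "_", normalize_token(name)) or "unnamed"


def canonicalize_names(
    variants: Iterable[str],
    threshold: float = 0.85,
    overrides: Mapping[str, str] | None = None,
) -> NameClusterMap:
    """Cluster institution name variants into canonical entities.

    Single-linkage clustering over :func:`name_similarity` at ``threshold``:
    two variants land in the same entity if a chain of pairwise-similar
    variants connects them, matching the transitive merging that truncated
    database names require. The canonical name of a cluster is its shortest
    variant (lexicographically smallest on ties), so the result does not
    depend on input order. ``overrides`` (variant -> canonical name) are
    applied last and always win.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in (0, 1], got {threshold}")
    originals = sorted(set(variants))
    norm = {v: normalize_token(v) for v in originals}

    parent = {v: v for v in originals}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            # deterministic union: smaller root wins
            if ry < rx:
                rx, ry = ry, rx
            parent[ry] = rx

    scores: dict[str, float] = {}
    for i, vi in enumerate(originals):
        ni = norm[vi]
        for vj in originals[i + 1 :]:
            nj = norm[vj]
            if ni == nj:
                union(vi, vj)
                continue
            # cheap upper bound: without containment, similarity cannot
            # exceed min/max length ratio
            la, lb = len(ni), len(nj)
            if min(la, lb) / max(la, lb) < threshold:
                ta, tb = ni.split(" "), nj.split(" ")
                short, long = (ta, tb) if len(ta) < len(tb) else (tb, ta)
                if long[: len(short)] != short:
                    continue
            sim = name_similarity(ni, nj)
            if sim >= threshold:
                union(vi, vj)
                for v in (vi, vj):
                    scores[v] = max(scores.get(v, 0.0), sim)

    clusters: dict[str, list[str]] = {}
    for v in originals:
        clusters.setdefault(find(v), []).append(v)

    cmap = NameClusterMap()
    for members in clusters.values():
        canonical = min(members, key=lambda v: (len(v), v))
        cid = _canonical_slug(canonical)
        cmap.canonical_names[cid] = canonical
        for v in members:
            cmap.mapping[v] = cid
            cmap.scores[v] = scores.get(v, 1.0)

    if overrides:
        for variant, target in overrides.items():
            cid = cmap.mapping.get(target) or _canonical_slug(target)
            cmap.canonical_names.setdefault(cid, target)
            cmap.mapping[variant] = cid
            cmap.scores[variant] = 1.0
            cmap.manual.add(variant)
    return cmap


def assign_sector(
    canonical_name: str,
    keyword_rules: Sequence[tuple[str, str]] = DEFAULT_SECTOR_RULES,
    overrides: Mapping[str, str] | None = None,
) -> str:
    """Assign an operation sector to an institution name.

    Override (exact name match) first, then the first matching keyword
    rule on the normalized name, else ``"unknown"``; never raises.
    """
    if overrides and canonical_name in overrides:
        return overrides[canonical_name]
    norm = normalize_token(canonical_name)
    for pattern, sector in keyword_rules:
        if re.search(pattern, norm):
            return sector
    return "unknown"


def load_override_file(path: str | Path) -> dict[str, str]:
    """Two-column plain-text map (tab-separated): source -> target."""
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigurationError(f"{path}: expected 2 tab-separated columns: {line!r}")
        out[parts[0].strip()] = parts[1].strip()
    return out


def resolve_corpus(
    corpus: Corpus,
    threshold: float = 0.85,
    name_overrides: Mapping[str, str] | None = None,
    sector_overrides: Mapping[str, str] | None = None,
    alias_table: Mapping[str, str] | None = None,
    keyword_rules: Sequence[tuple[str, str]] = DEFAULT_SECTOR_RULES,
) -> tuple[dict[str, Institution], NameClusterMap]:
    """Run full entity resolution over a corpus, in place.

    Populates ``parsed_country`` and ``canonical_id`` on every mention and
    returns the institution registry (canonical_id -> Institution) together
    with the name-cluster map. An institution's country is the majority
    country over its mentions; its region flag follows the ISO region table.
    """
    for rec in corpus:
        for m in rec.mentions:
            m.parsed_country = parse_country(m.raw_text, alias_table)

    variants = sorted({m.raw_institution for rec in corpus for m in rec.mentions})
    cmap = canonicalize_names(variants, threshold=threshold, overrides=name_overrides)

    country_votes: dict[str, dict[str, int]] = {}
    years: dict[str, set[int]] = {}
    for rec in corpus:
        for m in rec.mentions:
            cid = cmap.canonical_of(m.raw_institution)
            m.canonical_id = cid
            years.setdefault(cid, set()).add(rec.year)
            if m.parsed_country != UNRESOLVED:
                votes = country_votes.setdefault(cid, {})
                votes[m.parsed_country] = votes.get(m.parsed_country, 0) + 1

    registry: dict[str, Institution] = {}
    for cid, name in cmap.canonical_names.items():
        if cid not in years:
            continue  # override target never mentioned
        votes = country_votes.get(cid, {})
        country = max(sorted(votes), key=votes.get) if votes else UNRESOLVED
        registry[cid] = Institution(
            canonical_id=cid,
            canonical_name=name,
            country=country,
            is_african=countries.is_african(country),
            sector=assign_sector(name, keyword_rules, sector_overrides),
            first_pub_year=min(years[cid]),
            active_years=years[cid],
        )
    corpus.log(
        f"resolve_corpus: {len(variants)} name variants -> {len(registry)} institutions "
        f"(threshold={threshold})"
    )
    return registry, cmap
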