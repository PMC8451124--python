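"""Publication records: data model, tabular I/O and corpus-level filters.

A corpus is a set of publications, each carrying its year, author count and
the raw author-affiliation address strings. Two exclusion rules operate at
this level: dropping records with no affiliation in the target region, and
dropping very large collaborations (more than ``max_authors`` authors),
whose co-authorship says little about pairwise institutional relations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

from .countries import UNRESOLVED
from .errors import ConfigurationError, CorpusReadError, UnresolvedCountryError

#: Default number of authors above which a publication is excluded.
MAX_AUTHORS_DEFAULT = 20


@dataclass
class AffiliationMention:
    """One raw author-affiliation address on one publication."""

    raw_text: str
    parsed_country: str = UNRESOLVED  # ISO alpha-2 or UNRESOLVED
    raw_institution: str = ""  # leading institution substring of the address
    canonical_id: str | None = None  # assigned by entity resolution

    def __post_init__(self):
        if not self.raw_text:
            raise ValueError("raw_text must be non-empty")
        if not self.raw_institution:
            self.raw_institution = self.raw_text.split(",")[0].strip()


@dataclass
class PublicationRecord:
    pub_id: str
    title: str
    year: int
    author_count: int
    mentions: list[AffiliationMention]

    def __post_init__(self):
        if self.year <= 0:
            raise ValueError(f"{self.pub_id}: year must be positive")
        if self.author_count < 1:
            raise ValueError(f"{self.pub_id}: author_count must be >= 1")
        if not self.mentions:
            raise ValueError(f"{self.pub_id}: mentions must be non-empty")

    @property
    def institution_count(self) -> int:
        """Distinct resolved institutions, falling back to distinct raw names."""
        ids = {m.canonical_id for m in self.mentions if m.canonical_id}
        if ids:
            return len(ids)
        return len({m.raw_institution for m in self.mentions})

    def institution_ids(self) -> set[str]:
        return {m.canonical_id for m in self.mentions if m.canonical_id is not None}


@dataclass
class Corpus:
    """Publication records keyed by pub_id, with filter provenance."""

    records: dict[str, PublicationRecord] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PublicationRecord]:
        return iter(self.records.values())

    def years(self) -> list[int]:
        return sorted({r.year for r in self})

    def log(self, message: str) -> None:
        self.provenance.append(message)


@dataclass(frozen=True)
class ColumnMap:
    """Column-name mapping for tabular input files.

    ``author_count`` may be absent, in which case the number of affiliation
    addresses on the row stands in for the author count.
    """

    pub_id: str = "pub_id"
    year: str = "year"
    addresses: str = "addresses"
    title: str | None = "title"
    author_count: str | None = "author_count"
    address_delimiter: str = ";"
    csv_delimiter: str = ","


def read_corpus(
    path: str | Path,
    dialect: ColumnMap = ColumnMap(),
    strict: bool = True,
) -> Corpus:
    """Read a delimited text file into a :class:`Corpus`.

    One publication per row; the address cell holds one or more affiliation
    strings separated by ``dialect.address_delimiter``. Malformed rows are
    collected with their row numbers; with ``strict=True`` any malformed row
    aborts the read, otherwise such rows are skipped and logged in provenance.
    """
    path = Path(path)
    corpus = Corpus()
    errors: list[tuple[int, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.csv_delimiter)
        header = reader.fieldnames or []
        required = [dialect.pub_id, dialect.year, dialect.addresses]
        missing = [c for c in required if c not in header]
        if missing:
            raise ConfigurationError(
                f"{path}: mapped column(s) {missing} not in header {header}"
            )
        for rownum, row in enumerate(reader, start=2):
            try:
                corpus_add_row(corpus, row, dialect)
            except ValueError as exc:
                errors.append((rownum, str(exc)))
    if errors:
        if strict:
            raise CorpusReadError(errors)
        for rownum, msg in errors:
            corpus.log(f"skipped row {rownum}: {msg}")
    corpus.log(f"read {len(corpus)} records from {path.name}")
    return corpus


def corpus_add_row(corpus: Corpus, row: dict, dialect: ColumnMap) -> None:
    pub_id = (row.get(dialect.pub_id) or "").strip()
    if not pub_id:
        raise ValueError("empty publication id")
    if pub_id in corpus.records:
        raise ValueError(f"duplicate pub_id {pub_id!r}")
    year_text = (row.get(dialect.year) or "").strip()
    try:
        year = int(year_text)
    except ValueError:
        raise ValueError(f"unparseable year {year_text!r}") from None
    addresses = [
        a.strip()
        for a in (row.get(dialect.addresses) or "").split(dialect.address_delimiter)
        if a.strip()
    ]
    if not addresses:
        raise ValueError("empty address cell")
    title = (row.get(dialect.title) or "").strip() if dialect.title else ""
    if dialect.author_count and (row.get(dialect.author_count) or "").strip():
        try:
            author_count = int(row[dialect.author_count])
        except ValueError:
            raise ValueError(
                f"unparseable author count {row[dialect.author_count]!r}"
            ) from None
    else:
        author_count = len(addresses)
    corpus.records[pub_id] = PublicationRecord(
        pub_id=pub_id,
        title=title,
        year=year,
        author_count=author_count,
        mentions=[AffiliationMention(raw_text=a) for a in addresses],
    )


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus as line-delimited JSON (one record per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"provenance": corpus.provenance}) + "\n")
        for rec in corpus:
            fh.write(
                json.dumps(
                    {
                        "pub_id": rec.pub_id,
                        "title": rec.title,
                        "year": rec.year,
                        "author_count": rec.author_count,
                        "mentions": [
                            {
                                "raw_text": m.raw_text,
                                "parsed_country": m.parsed_country,
                                "raw_institution": m.raw_institution,
                                "canonical_id": m.canonical_id,
                            }
                            for m in rec.mentions
                        ],
                    }
                )
                + "\n"
            )


def read_corpus_jsonl(path: str | Path) -> Corpus:
    """Inverse of :func:`write_corpus`."""
    corpus = Corpus()
    with Path(path).open(encoding="utf-8") as fh:
        first = json.loads(fh.readline())
        corpus.provenance = list(first.get("provenance", []))
        for line in fh:
            obj = json.loads(line)
            corpus.records[obj["pub_id"]] = PublicationRecord(
                pub_id=obj["pub_id"],
                title=obj["title"],
                year=obj["year"],
                author_count=obj["author_count"],
                mentions=[AffiliationMention(**m) for m in obj["mentions"]],
            )
    return corpus


def _subset(corpus: Corpus, keep: Iterable[str], note: str) -> Corpus:
    keep = set(keep)
    out = Corpus(
        records={pid: corpus.records[pid] for pid in corpus.records if pid in keep},
        provenance=list(corpus.provenance),
    )
    out.log(note)
    return out


def filter_no_target_region(
    corpus: Corpus,
    region_predicate: Callable[[str], bool],
    allow_unresolved: bool = False,
) -> tuple[Corpus, int]:
    """Keep records with at least one mention in the target region.

    All mentions must already carry a parsed country; unresolved countries
    abort with the affected pub_ids unless ``allow_unresolved`` (unresolved
    mentions then simply never satisfy the predicate).
    """
    if not allow_unresolved:
        bad = {
            r.pub_id
            for r in corpus
            if any(m.parsed_country == UNRESOLVED for m in r.mentions)
        }
        if bad:
            raise UnresolvedCountryError(bad)
    keep = [
        r.pub_id
        for r in corpus
        if any(
            m.parsed_country != UNRESOLVED and region_predicate(m.parsed_country)
            for m in r.mentions
        )
    ]
    removed = len(corpus) - len(keep)
    out = _subset(
        corpus, keep, f"filter_no_target_region: removed {removed} record(s)"
    )
    return out, removed


def filter_large_teams(
    corpus: Corpus, max_authors: int = MAX_AUTHORS_DEFAULT
) -> tuple[Corpus, int]:
    """Drop records with strictly more than ``max_authors`` authors."""
    if max_authors < 1:
        raise ConfigurationError(f"max_authors must be >= 1, got {max_authors}")
    keep = [r.pub_id for r in corpus if r.author_count <= max_authors]
    removed = len(corpus) - len(keep)
    out = _subset(
        corpus,
        keep,
        f"filter_large_teams(>{max_authors} authors): removed {removed} record(s)",
    )
    return out, removed
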