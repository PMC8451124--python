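"""Synthetic bibliographic corpora with known ground truth.

The generator emulates the statistical structure of a growing two-region
(Africa / non-Africa) evidence-synthesis publication system over a span
of years, so that every pipeline stage — country parsing, name
clustering, filtering, window networks, mixing indices, centrality — can
be exercised against planted truth without any external dataset.

Generative model, per paper in year y:

1. with probability ``africa_free_rate`` the paper is a planted
   "false positive" with no African affiliation at all (these exercise
   the target-region filter and are dropped by it);
2. otherwise a seed institution is drawn (African with probability
   ``p_african_seed``) from the institutions that have entered the system
   by year y, hubs weighted ``hub_weight`` : 1;
3. the team size is 1 + a negative-binomial count truncated at
   ``team_cap`` - 1 (defaults tuned to a mean near 3.6-4.1 and SD near
   2.7-2.8), except that with probability ``large_team_rate`` the paper
   is a mega-collaboration with more than ``team_cap`` authors (these
   exercise the large-team filter);
4. each partner matches the seed's region with probability
   ``p_regional(y)`` and is drawn from that region's pool (hub-weighted,
   without replacement);
5. each mention renders as "Name, City, Country"; with probability
   ``name_noise_rate`` the institution name is corrupted (suffix
   qualifier or an in-place typo), mirroring the kinds of variants
   bibliographic databases produce.

Hubs are designated, not emergent: deterministic testability of the
centrality ranking beats realism here. All randomness flows from the
mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import yaml

from . import countries
from .errors import ConfigurationError
from .records import AffiliationMention, Corpus, PublicationRecord

_SYLLABLES = (
    "ka", "ru", "ma", "to", "be", "ni", "sa", "lo", "du", "we",
    "fi", "go", "han", "jo", "pe", "qui", "ras", "tu", "vo", "zim",
)

_SUFFIXES = ("Hlth Sci", "Sch Med", "Fac Sci", "Dept Biol")

_NAME_TEMPLATES = {
    "university": "Univ {place}",
    "hospital": "{place} Gen Hosp",
    "government": "Minist Hlth {place}",
    "intergovernmental": "United Nations Off {place}",
    "research_institute": "Inst Med Res {place}",
    "private": "{place} Pharma Ltd",
    "nonprofit": "{place} Hlth Fdn",
    "research_network": "{place} Evidence Network",
}

#: Rendered country spellings that exercise the alias table.
_COUNTRY_ALIASES = {"US": "USA", "GB": "UK", "TZ": "Tanzania", "CI": "Ivory Coast"}

DEFAULT_SECTOR_PROBS = {
    "university": 0.55,
    "hospital": 0.12,
    "government": 0.06,
    "intergovernmental": 0.02,
    "research_institute": 0.12,
    "private": 0.04,
    "nonprofit": 0.06,
    "research_network": 0.03,
}

_NONAFRICAN_POOL = (
    "US", "GB", "NL", "CH", "DE", "FR", "CA", "AU", "BE", "SE",
    "IT", "ES", "CN", "IN", "BR", "NO", "DK", "IE", "JP", "KR",
)
_AFRICAN_POOL = (
    "ZA", "EG", "UG", "NG", "ET", "KE", "CM", "GH", "TZ", "MW",
    "ZW", "SN", "CI", "MA", "TN", "RW", "BW", "ZM", "CD", "BF",
)


@dataclass
class SynthConfig:
    """Study-shaped defaults: year span, growth, team sizes, mixing, noise."""

    seed: int  # mandatory; no implicit entropy
    first_year: int = 2008
    last_year: int = 2019
    african_start: int = 31
    african_end: int = 510
    nonafrican_start: int = 40
    nonafrican_end: int = 1000
    papers_start: int = 26
    papers_end: int = 917
    team_mean: float = 3.8  # institutions per paper, pre-truncation target
    team_sd: float = 2.75
    team_cap: int = 20
    large_team_rate: float = 0.014  # mega-collaborations, > team_cap authors
    p_regional: float | tuple[float, float] = (0.20, 0.30)  # partner matches seed region
    p_african_seed: float = 1.0  # seed region for non-planted papers
    africa_free_rate: float = 0.014  # planted papers with no African mention
    single_year_rate: float = 0.69  # institutions active in exactly one year
    name_noise_rate: float = 0.15
    sector_probs: dict = field(default_factory=lambda: dict(DEFAULT_SECTOR_PROBS))
    n_hubs_african: int = 4
    n_hubs_nonafrican: int = 3
    hub_weight: float = 30.0

    def __post_init__(self):
        for name in (
            "large_team_rate", "p_african_seed", "africa_free_rate",
            "single_year_rate", "name_noise_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for p in self._p_regional_pair():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"p_regional must be in [0, 1], got {p}")
        if self.last_year < self.first_year:
            raise ConfigurationError("last_year before first_year")
        if self.african_start < self.n_hubs_african:
            raise ConfigurationError("fewer starting African institutions than hubs")
        if self.nonafrican_start < self.n_hubs_nonafrican:
            raise ConfigurationError("fewer starting non-African institutions than hubs")
        if abs(sum(self.sector_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("sector_probs must sum to 1")
        if self.team_sd**2 <= self.team_mean - 1.0:
            raise ConfigurationError(
                "team_sd^2 must exceed team_mean - 1 (overdispersed count model)"
            )

    # ---- schedules -------------------------------------------------------
    def years(self) -> list[int]:
        return list(range(self.first_year, self.last_year + 1))

    def _geometric(self, start: int, end: int) -> list[int]:
        ys = self.years()
        if len(ys) == 1:
            return [start]
        ratio = (end / start) ** (1.0 / (len(ys) - 1))
        return [max(1, round(start * ratio**i)) for i in range(len(ys))]

    def papers_per_year(self) -> dict[int, int]:
        return dict(zip(self.years(), self._geometric(self.papers_start, self.papers_end)))

    def institutions_per_year(self, region: str) -> dict[int, int]:
        """Cumulative population size per year for one region."""
        if region == "african":
            sched = self._geometric(self.african_start, self.african_end)
        else:
            sched = self._geometric(self.nonafrican_start, self.nonafrican_end)
        return dict(zip(self.years(), sched))

    def _p_regional_pair(self) -> tuple[float, float]:
        if isinstance(self.p_regional, (int, float)):
            return (float(self.p_regional), float(self.p_regional))
        return (float(self.p_regional[0]), float(self.p_regional[1]))

    def p_regional_in(self, year: int) -> float:
        lo, hi = self._p_regional_pair()
        ys = self.years()
        if len(ys) == 1:
            return lo
        frac = (year - ys[0]) / (len(ys) - 1)
        return lo + (hi - lo) * frac

    # ---- team-size distribution -----------------------------------------
    def _nb_params(self) -> tuple[float, float]:
        """(r, p) of the negative binomial for team size minus one."""
        m = self.team_mean - 1.0
        var = self.team_sd**2
        r = m * m / (var - m)
        return r, r / (r + m)

    def team_size_pmf(self) -> np.ndarray:
        """pmf of the truncated team size on {1, ..., team_cap}."""
        r, p = self._nb_params()
        kmax = self.team_cap - 1
        pmf = np.empty(kmax + 1)
        pmf[0] = p**r
        for k in range(kmax):
            pmf[k + 1] = pmf[k] * (k + r) / (k + 1) * (1.0 - p)
        pmf /= pmf.sum()
        return pmf  # index k -> P(team == k + 1)


@dataclass
class SynthInstitution:
    inst_id: str
    name: str
    city: str
    country: str
    african: bool
    sector: str
    entry_year: int
    single_year: bool  # restricted to its entry year only
    hub: bool


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    institutions: dict[str, SynthInstitution]
    partition: dict[str, set]  # true name -> set of emitted variants
    variant_to_name: dict[str, str]
    paper_members: dict[str, list]  # pub_id -> institution ids
    large_team_ids: set
    africa_free_ids: set
    designated_single_year: set
    expected_mixing: dict  # window label -> analytic expectation

    def hub_ids(self, african: bool | None = None) -> set:
        return {
            i.inst_id
            for i in self.institutions.values()
            if i.hub and (african is None or i.african == african)
        }


# --------------------------------------------------------------- expectation

def expected_mixing(config: SynthConfig) -> dict[str, dict]:
    """Analytic expectation of the Africa-internal tie structure per window.

    For a retained paper (mega-collaborations are excluded by the
    large-team filter, planted Africa-free papers by the region filter)
    with team size T and seed region drawn with probability
    ``p_african_seed``, each of the m = T - 1 partners independently
    matches the seed's region with probability p. Expected
    Africa-Africa and Africa-nonAfrica pair counts follow from binomial
    moments of the number of African partners; weighting by the papers
    per year gives per-window expectations of I_A, E_A counted as
    pair-publication incidences, and the implied regionalization index.
    """
    pmf = config.team_size_pmf()
    s = config.p_african_seed
    out: dict[str, dict] = {}
    years = config.years()
    papers = config.papers_per_year()
    for y0 in years[:-1]:
        i_a = e_a = 0.0
        for year in (y0, y0 + 1):
            p = config.p_regional_in(year)
            aa_paper = an_paper = 0.0
            for k, prob in enumerate(pmf):
                m = k  # partners = team size - 1
                # African seed: k_a ~ Bin(m, p) African partners
                ek, ek2 = m * p, m * p * (1 - p) + (m * p) ** 2
                aa_af = (ek + ek2) / 2.0  # E[C(1 + k_a, 2)]
                an_af = m + (m - 1) * ek - ek2  # E[(1 + k_a)(m - k_a)]
                # non-African seed: k_a ~ Bin(m, 1 - p)
                q = 1 - p
                fk, fk2 = m * q, m * q * (1 - q) + (m * q) ** 2
                aa_na = (fk2 - fk) / 2.0  # E[C(k_a, 2)]
                an_na = (1 + m) * fk - fk2  # E[k_a (1 + m - k_a)]
                aa_paper += prob * (s * aa_af + (1 - s) * aa_na)
                an_paper += prob * (s * an_af + (1 - s) * an_na)
            n_retained = papers[year] * (1 - config.africa_free_rate) * (
                1 - config.large_team_rate
            )
            i_a += n_retained * aa_paper
            e_a += n_retained * an_paper
        denom = 2 * i_a + e_a
        r = (2 * i_a - e_a) / denom if denom > 0 else None
        out[f"{y0}-{y0 + 1}"] = {
            "i_a": i_a,
            "e_a": e_a,
            "internal_share": i_a / (i_a + e_a) if i_a + e_a > 0 else None,
            "regionalization": r,
        }
    return out


# --------------------------------------------------------------- generation

def _make_place(rng: np.random.Generator, constraints=()) -> str:
    """A pronounceable synthetic place name.

    ``constraints`` is a sequence of ``(used_names, min_dist)`` pairs; the
    new name keeps an edit distance of at least ``min_dist`` from every
    name in each list (and is appended to the first list), so institution
    names templated on these places cannot merge spuriously under fuzzy
    clustering.
    """
    import edlib

    min_len = max([d for _, d in constraints] + [4]) + 4
    for _ in range(5000):
        parts = [str(rng.choice(_SYLLABLES)) for _ in range(3)]
        while sum(map(len, parts)) < min_len:
            parts.append(str(rng.choice(_SYLLABLES)))
        place = "".join(parts).capitalize()
        ok = all(
            edlib.align(place.lower(), u.lower(), task="distance")["editDistance"]
            >= min_dist
            for used, min_dist in constraints
            for u in used
        )
        if ok:
            if constraints:
                constraints[0][0].append(place)
            return place
    raise ConfigurationError("place-name space exhausted; reduce institution counts")


#: extra distance margin isolating hub names from every other same-template name
_HUB_MARGIN = 4


def _template_min_dist(template: str) -> int:
    """Minimum place distance so same-template names stay below the default
    clustering threshold even after suffix/typo corruption."""
    fixed = len(template.replace("{place}", ""))
    return int(0.15 * (fixed + 12)) + 1


def _corrupt_name(rng: np.random.Generator, name: str) -> str:
    """Database-style variant: trailing qualifier, or a typo in the last token."""
    if rng.random() < 0.5 or len(name) < 12:
        return f"{name} {_SUFFIXES[rng.integers(0, len(_SUFFIXES))]}"
    chars = list(name)
    tail_start = name.rfind(" ") + 1
    if tail_start >= len(name) - 1:
        tail_start = max(1, len(name) - 5)
    pos = int(rng.integers(tail_start, len(name)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    repl = alphabet[rng.integers(0, 26)]
    if chars[pos].lower() == repl:
        repl = alphabet[(alphabet.index(repl) + 1) % 26]
    chars[pos] = repl
    return "".join(chars)


def _build_institutions(config: SynthConfig, rng: np.random.Generator):
    insts: dict[str, SynthInstitution] = {}
    used_places: dict[str, list[str]] = {s: [] for s in _NAME_TEMPLATES}
    hub_places: list[str] = []
    sectors = list(config.sector_probs)
    sector_p = np.array([config.sector_probs[s] for s in sectors])
    counter = 0
    for region, african in (("african", True), ("nonafrican", False)):
        cumsched = config.institutions_per_year(region)
        prev = 0
        n_hubs = config.n_hubs_african if african else config.n_hubs_nonafrican
        for year in config.years():
            entering = cumsched[year] - prev
            prev = cumsched[year]
            for _ in range(max(0, entering)):
                counter += 1
                inst_id = f"S{counter:05d}"
                hub = year == config.first_year and n_hubs > 0
                if hub:
                    n_hubs -= 1
                    sector = "university"  # hubs are large universities
                else:
                    sector = sectors[rng.choice(len(sectors), p=sector_p)]
                template = _NAME_TEMPLATES[sector]
                base_dist = _template_min_dist(template)
                constraints = [
                    (used_places[sector], base_dist),
                    (hub_places, base_dist + _HUB_MARGIN),
                ]
                place = _make_place(rng, constraints)
                if hub:
                    hub_places.append(place)
                pool = _AFRICAN_POOL if african else _NONAFRICAN_POOL
                insts[inst_id] = SynthInstitution(
                    inst_id=inst_id,
                    name=template.format(place=place),
                    city=_make_place(rng),
                    country=str(rng.choice(pool)),
                    african=african,
                    sector=sector,
                    entry_year=year,
                    single_year=(not hub) and rng.random() < config.single_year_rate,
                    hub=hub,
                )
    return insts


def _eligible(insts, year: int, african: bool) -> list[SynthInstitution]:
    return [
        i
        for i in insts.values()
        if i.african == african
        and i.entry_year <= year
        and (not i.single_year or i.entry_year == year)
    ]


def _sample_without_replacement(rng, pool, weights, k, exclude):
    chosen = []
    idx = [i for i, inst in enumerate(pool) if inst.inst_id not in exclude]
    if not idx:
        return chosen
    w = np.array([weights[i] for i in idx], dtype=float)
    k = min(k, len(idx))
    picks = rng.choice(len(idx), size=k, replace=False, p=w / w.sum())
    for p in picks:
        chosen.append(pool[idx[p]])
    return chosen


def generate_corpus(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a reproducible corpus and its ground truth."""
    rng = np.random.default_rng(config.seed)
    insts = _build_institutions(config, rng)
    pmf = config.team_size_pmf()

    partition: dict[str, set] = {i.name: {i.name} for i in insts.values()}
    variant_to_name: dict[str, str] = {i.name: i.name for i in insts.values()}
    paper_members: dict[str, list] = {}
    large_team_ids: set = set()
    africa_free_ids: set = set()

    corpus = Corpus()
    corpus.log(f"synthetic corpus (seed={config.seed})")
    pub_counter = 0
    for year in config.years():
        pools = {
            True: _eligible(insts, year, True),
            False: _eligible(insts, year, False),
        }
        weights = {
            afr: [config.hub_weight if i.hub else 1.0 for i in pool]
            for afr, pool in pools.items()
        }
        p_reg = config.p_regional_in(year)
        for _ in range(config.papers_per_year()[year]):
            pub_counter += 1
            pub_id = f"P{pub_counter:05d}"
            africa_free = rng.random() < config.africa_free_rate
            mega = rng.random() < config.large_team_rate
            if africa_free:
                seed_african = False
            else:
                seed_african = rng.random() < config.p_african_seed
            if mega:
                author_count = int(rng.integers(config.team_cap + 1, 104))
                team_size = int(min(rng.integers(8, 40), author_count))
            else:
                team_size = 1 + int(rng.choice(len(pmf), p=pmf))
                author_count = team_size
            members = _sample_without_replacement(
                rng, pools[seed_african], weights[seed_african], 1, set()
            )
            taken = {m.inst_id for m in members}
            for _ in range(team_size - 1):
                if africa_free:
                    partner_african = False
                else:
                    partner_african = (
                        seed_african
                        if rng.random() < p_reg
                        else not seed_african
                    )
                pick = _sample_without_replacement(
                    rng, pools[partner_african], weights[partner_african], 1, taken
                ) or _sample_without_replacement(
                    rng, pools[not partner_african], weights[not partner_african], 1, taken
                )
                if pick:
                    members.extend(pick)
                    taken.add(pick[0].inst_id)
            mentions = []
            for inst in members:
                name = inst.name
                if rng.random() < config.name_noise_rate:
                    name = _corrupt_name(rng, inst.name)
                    partition[inst.name].add(name)
                    variant_to_name[name] = inst.name
                country_text = (
                    _COUNTRY_ALIASES[inst.country]
                    if inst.country in _COUNTRY_ALIASES and rng.random() < 0.3
                    else countries.country_name(inst.country)
                )
                mentions.append(
                    AffiliationMention(raw_text=f"{name}, {inst.city}, {country_text}")
                )
            corpus.records[pub_id] = PublicationRecord(
                pub_id=pub_id,
                title=f"Synthetic evidence synthesis {pub_counter}",
                year=year,
                author_count=author_count,
                mentions=mentions,
            )
            paper_members[pub_id] = [m.inst_id for m in members]
            if mega:
                large_team_ids.add(pub_id)
            if not any(m.african for m in members):
                africa_free_ids.add(pub_id)

    truth = GroundTruth(
        institutions=insts,
        partition=partition,
        variant_to_name=variant_to_name,
        paper_members=paper_members,
        large_team_ids=large_team_ids,
        africa_free_ids=africa_free_ids,
        designated_single_year={i.inst_id for i in insts.values() if i.single_year},
        expected_mixing=expected_mixing(config),
    )
    return corpus, truth


def observed_mixing(truth: GroundTruth, corpus: Corpus) -> dict[str, dict]:
    """Pair-publication incidence counts of I_A / E_A per window, from truth.

    Counts the same quantity :func:`expected_mixing` predicts (incidences,
    not unique pairs), over the retained papers of the corpus.
    """
    insts = truth.institutions
    years = sorted({r.year for r in corpus})
    per_year: dict[int, list[float]] = {y: [0.0, 0.0] for y in years}
    for rec in corpus:
        if rec.pub_id in truth.large_team_ids or rec.pub_id in truth.africa_free_ids:
            continue
        members = truth.paper_members[rec.pub_id]
        n_a = sum(1 for m in members if insts[m].african)
        n_n = len(members) - n_a
        per_year[rec.year][0] += n_a * (n_a - 1) / 2.0
        per_year[rec.year][1] += n_a * n_n
    out = {}
    for y0 in years[:-1]:
        i_a = per_year[y0][0] + per_year[y0 + 1][0]
        e_a = per_year[y0][1] + per_year[y0 + 1][1]
        denom = 2 * i_a + e_a
        out[f"{y0}-{y0 + 1}"] = {
            "i_a": i_a,
            "e_a": e_a,
            "internal_share": i_a / (i_a + e_a) if i_a + e_a else None,
            "regionalization": (2 * i_a - e_a) / denom if denom else None,
        }
    return out


def rand_index(labels_a: dict, labels_b: dict) -> float:
    """Rand index between two partitions given as item -> cluster label."""
    items = sorted(labels_a)
    if sorted(labels_b) != items:
        raise ValueError("partitions must cover the same items")
    n = len(items)
    if n < 2:
        return 1.0
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = labels_a[items[i]] == labels_a[items[j]]
            same_b = labels_b[items[i]] == labels_b[items[j]]
            agree += same_a == same_b
    return agree / (n * (n - 1) / 2)


# --------------------------------------------------------------- file bundle

def write_synth_bundle(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit corpus CSV (the tabular format read_corpus expects), ground-truth
    sidecar JSON, and the config with its seed."""
    import csv as _csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus, truth = generate_corpus(config)
    paths = {
        "corpus": outdir / "synth_corpus.csv",
        "truth": outdir / "synth_truth.json",
        "config": outdir / "synth_config.yaml",
    }
    with paths["corpus"].open("w", newline="", encoding="utf-8") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["pub_id", "title", "year", "author_count", "addresses"])
        for rec in corpus:
            writer.writerow(
                [
                    rec.pub_id,
                    rec.title,
                    rec.year,
                    rec.author_count,
                    "; ".join(m.raw_text for m in rec.mentions),
                ]
            )
    truth_obj = {
        "institutions": {k: asdict(v) for k, v in truth.institutions.items()},
        "partition": {k: sorted(v) for k, v in truth.partition.items()},
        "paper_members": truth.paper_members,
        "large_team_ids": sorted(truth.large_team_ids),
        "africa_free_ids": sorted(truth.africa_free_ids),
        "designated_single_year": sorted(truth.designated_single_year),
        "expected_mixing": truth.expected_mixing,
    }
    paths["truth"].write_text(json.dumps(truth_obj, indent=1), encoding="utf-8")
    paths["config"].write_text(yaml.safe_dump(asdict(config)), encoding="utf-8")
    return paths
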