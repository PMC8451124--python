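# Methods

This note documents the analysis model implemented by `coauthnet`, the
conventions and numerical choices behind each stage, what the synthetic
corpus generator does and does not emulate, and the package's known
limitations.

## Data model and filters

A corpus is a set of publication records, each with a unique identifier,
a calendar year, an author count and one or more raw author-affiliation
address strings ("mentions"). Institutions — not authors — are the unit
of analysis: every distinct institution on a paper is one entity,
regardless of how many authors list it, and an author with several
affiliations contributes each of them.

Two corpus-level exclusion rules are applied after entity resolution:

* **target-region filter** — records with no affiliation in the target
  region (default: Africa) are removed; these arise in practice as
  false positives of affiliation-field searches, e.g. when a region's
  country name appears mid-address ("South Africa House, London").
  Records with unresolved countries abort the filter (listing the
  affected ids) unless explicitly allowed.
* **large-team filter** — records with strictly more than `max_authors`
  authors (default 20) are removed; a paper with exactly 20 authors is
  retained. Very large collaborations say little about pairwise
  institutional relations. The filter acts on the author count, not the
  institution count, which is tracked separately.

Both filters are idempotent, conserve records (`|in| = |out| + removed`)
and log their counts to the corpus provenance.

## Entity resolution

**Countries.** The comma-separated tokens of an address are scanned from
the end backward; the first token matching the ISO-3166 table wins, and
within a token the longest word-suffix that names a country is used (so
postal codes and state abbreviations before the country are ignored).
This terminal-first scan is what makes the target-region filter immune to
region names appearing mid-address. Common non-ISO spellings ("USA",
"UK", "Tanzania", …) are resolved through an editable alias table. The
country and alias tables are plain-text package data rather than a
third-party dependency's internal region taxonomy, because region
assignment must be stable and auditable; Africa membership is a pure
function of the alpha-2 code.

**Institution names.** The leading substring before the first comma is
the raw institution name. Names are normalized (case-folded, punctuation
stripped, whitespace collapsed) and clustered by single linkage at a
similarity threshold (default 0.85) under a composite similarity:

* 1.0 when one name's token sequence is a prefix of the other's — the
  containment case produced by database truncation and trailing
  campus/department qualifiers ("Univ Cape Town" vs
  "Univ Cape Town Hlth Sci");
* otherwise `1 − d/max(|a|, |b|)` with `d` the Levenshtein distance
  (computed with edlib).

Single linkage (rather than complete linkage) matches the transitive
merging that chains of truncated variants require. The canonical name of
a cluster is its shortest variant, ties broken lexicographically, which
makes the partition independent of input order. The 0.85 default merges
the truncation example above while keeping distinct universities in the
same city apart; no universally correct threshold exists, which is why
every merge is written with its score to an audit CSV and why manual
override files (variant → canonical) are applied last and always win.

**Sectors.** Eight operation sectors (university, hospital, government,
intergovernmental, research institute, private, nonprofit, research
network) plus `unknown` are assigned by an ordered keyword-rule list on
the normalized name (first match wins), with an exact-name override map
checked first. The rule set is a keyword reconstruction, not an
authoritative registry — abbreviated names without a keyword ("LSHTM")
fall to `unknown` and are expected to be completed via overrides, which
is also how a curated analysis would record its manual coding.

An institution's country is the majority vote over its mentions; its
first publication year and active-year set are recomputed from whatever
corpus is being analyzed (i.e., after filtering).

## Window networks

Networks are built per 2-year window stepped by one year (configurable),
so a 2008–2019 span yields eleven overlapping networks. Rules:

* **cumulative entry** — an institution is a node in every window from
  its first publication onward, publishing in the window or not;
  isolates are retained deliberately, because they belong in LCC
  percentages and in the `n` of normalized centralities;
* **single-year restriction** — institutions active in exactly one
  calendar year appear only in the (up to two) windows containing that
  year; they are not removed retroactively from their own year;
* **edges** — two distinct institutions are tied if they co-appear on at
  least one publication dated within the window. Graphs are simple: no
  self-loops (repeated mentions of one institution on a paper add
  nothing) and no parallel edges. The number of joint publications is
  kept as an edge weight but all analyses are unweighted, and tie counts
  count unique pairs per window, not pair–publication incidences.

## Metrics

* **LCC / path length** — the largest connected component (size ties
  broken toward the lexicographically smallest member list, for
  determinism); the share of a group's institutions inside it (isolates
  in the denominator); and the mean unweighted shortest-path length over
  unordered pairs of group members within the LCC. Both a whole-network
  and an Africa-only (induced subgraph) variant are reported, and the
  path-length average is over African pairs by default (an all-pairs
  variant is available).
* **Mixing** — every unique edge is classified into exactly one of
  `I_A` (Africa–Africa), `E_A` (Africa–non-Africa), `I_N`
  (non-Africa–non-Africa). The E-I index uses `E = E_A`,
  `I = I_A + I_N`; the regionalization index is
  `(2·I_A − E_A)/(2·I_A + E_A)`; the internal-tie proportion is
  `(1 + R)/2`. Windows with a zero denominator yield an explicit missing
  value, never a silent 0.
* **Centrality** — unweighted degree, and exact Brandes betweenness over
  unordered pairs (pairs in different components contribute 0; no
  sampling). Normalization divides by the maximum possible for a node in
  a network with the same number of nodes — `n − 1` and
  `(n − 1)(n − 2)/2` — with `n` the full window node count including
  isolates; it is reported as undefined for `n < 2` (degree) or `n < 3`
  (betweenness). Within-region rankings use competition ranking
  ("1, 2, 2, 4"), and the central set contains every region institution
  reaching rank ≤ 3 (configurable) in either measure in any window.
* **Ego networks** — a node's local neighbourhood is its collaborators
  plus the ties among them. Component structure is computed with the ego
  removed (otherwise isolated collaborators and satellite components
  could never be seen). The neighbourhood subgraph may be restricted to
  a region for structural inspection, but composition percentages (share
  of African collaborators; share of nonacademic collaborators, i.e.,
  sector ≠ university, hospitals counting as nonacademic) are always
  over the full collaborator set; both readings are thus available
  side by side.

## Synthetic corpus generator

The generator emulates the statistical structure of a growing two-region
publication system so every stage can be tested against planted truth.
Defaults describe the study system the package was built around:

| parameter | default | meaning |
|---|---|---|
| years | 2008–2019 | twelve publication years, eleven windows |
| African institutions | 31 → 510 | geometric population growth |
| non-African institutions | 40 → 1000 | idem |
| papers/year | 26 → 917 | geometric growth, ≈3250 papers total |
| team size | 1 + NB, mean 3.8, SD 2.75, cap 20 | institutions per paper |
| `large_team_rate` | 0.014 | mega-papers with 21–103 authors |
| `p_regional` | 0.20 → 0.30 | partner matches the seed's region |
| `africa_free_rate` | 0.014 | planted papers with no African member |
| `single_year_rate` | 0.69 | institutions active in exactly one year |
| `name_noise_rate` | 0.15 | corrupted name variants |
| hubs | 4 African + 3 non-African, weight 30 | designated central nodes |

Papers are assembled seed-first: a seed institution (African with
probability `p_african_seed`, default 1 — the corpus is defined by
region-affiliated publications), then a truncated negative-binomial team
size, then partners drawn hub-weighted from the seed's region with
probability `p_regional`, else from the other region. The negative
binomial is the standard overdispersed count model; one distribution
cannot hit mean ≈ 3.8, SD ≈ 2.75 *and* a 1.4 % heavy tail above 20
simultaneously, so mega-papers are an explicit mixture component.
`p_regional` ramping 0.20 → 0.30 yields external-to-internal tie ratios
in the 2.8–5 range and a rising regionalization index, the regime the
pipeline is meant to measure. Name corruption mirrors database variants:
trailing qualifiers ("Hlth Sci") and in-place typos; synthetic place
names are kept at a minimum edit distance (scaled to the name-template
length, with extra margin around hubs) so that distinct institutions
cannot merge at the default clustering threshold — the noise tests probe
variant recall, not an adversarial namespace.

`expected_mixing` gives the closed-form expectation of `I_A`/`E_A`
(counted as pair–publication incidences over retained papers) from the
binomial moments of the number of same-region partners, weighted by the
team-size pmf and papers-per-year schedule; parameter-recovery tests
compare generated corpora against it within Monte-Carlo error.

**What the generator does not emulate.** Partner choice is uniform
within a region apart from hub weighting, so papers overlap in members
far more than real co-authorship (which clusters by geography and
discipline). Generated networks therefore percolate almost immediately —
LCC shares near 100 % from the first window — whereas real systems start
fragmented. Passing tests consequently validate the *computation* of
connectivity measures (against independent oracles), not the package's
ability to reproduce a real system's connectivity trajectory. Hubs are
designated rather than emergent, trading realism for deterministic
testability of the ranking rule. There is no citation structure, no
author-level identity, and no disciplinary topics.

## Numerical and reporting conventions

* All randomness flows from a mandatory integer seed; identical seeds
  give byte-identical corpora and report bundles.
* Undefined quantities (zero-tie windows, `n < 3` normalizations, empty
  groups) are signalled — as exceptions at the library surface and as
  missing values in reports — never coerced to 0.
* Ties are broken deterministically everywhere: lexicographic smallest
  for LCC ties and canonical names, shared minimum for rank ties.
* Printed two-decimal proportions use half-up rounding, the convention
  of the reference tables ((1 − 0.17)/2 = 0.415 prints as 0.42);
  floating-point bankers' rounding would print 0.41.
* Test problem sizes: oracle equivalence runs 1000 random graphs up to
  200 nodes; parameter recovery uses corpora of tens to a few hundred
  papers per year with a dozen replicate seeds per setting. These sizes
  give stable verdicts (3-standard-error bands for stochastic checks)
  while keeping the default suite fast.

## Limitations

* The similarity threshold and the sector keyword rules are heuristics;
  curated analyses should treat the audit CSV and override files as part
  of the workflow, not an afterthought.
* Tie counts follow the unique-pair reading; analyses that need
  pair–publication incidences can recover them from the edge weights.
* The reference dataset used by the original analysis is not
  redistributable, so the corpus-count reproduction test documents the
  expected values and fails in its absence rather than pretending to
  verify them.
* No author-level disambiguation, no external institution registries
  (ROR/GRID), no geocoding, no weighted or approximate centralities, no
  significance testing of the indices.
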