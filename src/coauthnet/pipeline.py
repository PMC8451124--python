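"""End-to-end pipeline orchestration: clean -> build -> metrics -> ego -> report.

Every stage output is a pure function of (input, config); re-running with
the same input and config reproduces the bundle bit-for-bit (timestamps
are kept out of the data files). Defaults reproduce the reference
analysis settings: 2-year windows stepped by one year over 2008-2019,
a 20-author ceiling, Africa as the target region, top-3 centrality rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import build, countries, ego, metrics, records, resolve
from .errors import PipelineError
from .records import ColumnMap, Corpus
from .synth import SynthConfig, generate_corpus


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_path: Optional[str] = None  # tabular corpus; exclusive with synth
    synth: Optional[SynthConfig] = None
    column_map: ColumnMap = field(default_factory=ColumnMap)
    first_year: int = 2008
    last_year: int = 2019
    window_len: int = 2
    step: int = 1
    similarity_threshold: float = 0.85
    max_authors: int = 20
    top_k: int = 3
    name_overrides_path: Optional[str] = None
    sector_overrides_path: Optional[str] = None
    outdir: str = "coauthnet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "synth" in obj and obj["synth"] is not None:
            obj["synth"] = SynthConfig(**obj["synth"])
        if "column_map" in obj and obj["column_map"] is not None:
            obj["column_map"] = ColumnMap(**obj["column_map"])
        return cls(**obj)


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run, with paths of everything written."""

    corpus: Corpus
    registry: dict
    series: build.NetworkSeries
    mixing: pd.DataFrame
    connectivity: pd.DataFrame
    centrality: pd.DataFrame
    central_set: set
    ego_table: pd.DataFrame
    country_counts: pd.DataFrame
    outdir: Path


def country_count_tables(corpus: Corpus, registry: dict) -> pd.DataFrame:
    """Per (year, country): number of publishing institutions and publications."""
    inst_rows: dict[tuple, set] = {}
    pub_rows: dict[tuple, set] = {}
    for rec in corpus:
        for m in rec.mentions:
            cid = m.canonical_id
            inst = registry.get(cid)
            country = inst.country if inst else m.parsed_country
            inst_rows.setdefault((rec.year, country), set()).add(cid)
            pub_rows.setdefault((rec.year, country), set()).add(rec.pub_id)
    rows = [
        {
            "year": year,
            "country": country,
            "is_african": countries.is_african(country),
            "n_institutions": len(inst_rows[(year, country)]),
            "n_publications": len(pub_rows[(year, country)]),
        }
        for (year, country) in sorted(inst_rows)
    ]
    return pd.DataFrame(rows)


def _load_input(config: RunConfig) -> Corpus:
    if (config.input_path is None) == (config.synth is None):
        raise PipelineError("ingest: provide exactly one of input_path or synth config")
    if config.synth is not None:
        corpus, _ = generate_corpus(config.synth)
        return corpus
    return records.read_corpus(config.input_path, config.column_map)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run all stages and write the report bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    corpus = _load_input(config)
    if len(corpus) == 0:
        raise PipelineError("ingest: corpus is empty")

    name_overrides = (
        resolve.load_override_file(config.name_overrides_path)
        if config.name_overrides_path
        else None
    )
    sector_overrides = (
        resolve.load_override_file(config.sector_overrides_path)
        if config.sector_overrides_path
        else None
    )
    try:
        registry, cmap = resolve.resolve_corpus(
            corpus,
            threshold=config.similarity_threshold,
            name_overrides=name_overrides,
            sector_overrides=sector_overrides,
        )
    except Exception as exc:  # noqa: BLE001 - stage context for the operator
        raise PipelineError(f"resolve: {exc}") from exc

    n_before = len(corpus)
    corpus, n_no_region = records.filter_no_target_region(
        corpus, countries.is_african, allow_unresolved=True
    )
    corpus, n_large = records.filter_large_teams(corpus, config.max_authors)
    corpus.log(
        f"filters: {n_before} records in; {n_no_region} without target-region "
        f"affiliation removed; {n_large} large-team (> {config.max_authors} authors) "
        f"removed; {len(corpus)} retained"
    )
    # recompute institution activity on the filtered corpus
    registry = {
        cid: inst for cid, inst in registry.items()
        if cid in build.active_years(corpus)
    }
    n_single = len(build.single_year_institutions(corpus))
    corpus.log(f"{n_single} single-year institutions (window-restricted nodes)")

    if len(corpus) == 0:
        raise PipelineError("build: no records left after filtering")
    try:
        series = build.build_series(
            corpus,
            registry,
            config.first_year,
            config.last_year,
            window_len=config.window_len,
            step=config.step,
        )
    except Exception as exc:
        raise PipelineError(f"build: {exc}") from exc

    build.write_series(series, outdir / "networks")
    mixing = metrics.mixing_series(series)
    connectivity = metrics.connectivity_series(series)
    central_set, centrality = metrics.rank_and_select_central(
        series, metrics.is_african_node, top_k=config.top_k
    )
    ego_table = ego.ego_composition_series(series, central_set)
    counts = country_count_tables(corpus, registry)

    mixing.to_csv(outdir / "mixing.csv", index=False)
    connectivity.to_csv(outdir / "connectivity.csv", index=False)
    centrality.to_csv(outdir / "centrality.csv", index=False)
    ego_table.to_csv(outdir / "ego_composition.csv", index=False)
    counts.to_csv(outdir / "country_counts.csv", index=False)
    cmap.write_report(outdir / "name_resolution.csv")
    (outdir / "provenance.log").write_text(
        "\n".join(corpus.provenance) + "\n", encoding="utf-8"
    )
    settings = asdict(config)
    settings["column_map"] = asdict(config.column_map)
    if config.synth is not None:
        settings["synth"] = asdict(config.synth)
    (outdir / "run_config.yaml").write_text(
        yaml.safe_dump(settings), encoding="utf-8"
    )

    return ReportBundle(
        corpus=corpus,
        registry=registry,
        series=series,
        mixing=mixing,
        connectivity=connectivity,
        centrality=centrality,
        central_set=central_set,
        ego_table=ego_table,
        country_counts=counts,
        outdir=outdir,
    )
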