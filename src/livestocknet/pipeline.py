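"""End-to-end orchestration: from input files (or synthetic data) to report
tables mirroring the analysis outputs.

Artifacts written to the output directory:

* ``table4_summary.csv``      descriptive movement summaries
* ``table5_metrics.csv``      network-level metrics, years as columns
* ``table6_zscores.csv``      observed-vs-ensemble z-scores + min ensemble p
* ``table7_components.csv``   GSCC / GWCC sizes per year
* ``table8_key_markets.csv``  top market per year and metric
* ``degree_fit.json``         heavy-tail fits of the overall network
* ``communities.csv``         community membership (most recent year)
* ``provenance.json``         counters, seeds and config echo

Numeric outputs are written unrounded; rounding is a display concern.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from livestocknet import __version__
from livestocknet.data_io import (
    MovementTable, read_edge_list, read_node_list, read_raw_entries,
    split_survey_entries, filter_movements, summarize_movements,
)
from livestocknet.graph_build import (
    STUDY_YEARS, build_yearly_networks, build_overall_network,
    degree_sequences,
)
from livestocknet.metrics import (
    metric_report, report_frame, connected_components, key_market_table,
)
from livestocknet.spatial import propinquity_test
from livestocknet.null_model import (
    generate_ensemble, z_scores, ensemble_propinquity,
    DEFAULT_SWAPS_PER_LINK,
)
from livestocknet.heavytail import (
    fit_discrete_power_law, gof_pvalue, fit_lognormal, vuong_compare,
    ccdf_table,
)
from livestocknet.communities import fast_greedy_communities
from livestocknet.synthetic import SyntheticConfig, generate_markets, \
    generate_movements

logger = logging.getLogger(__name__)

ALL_STAGES = ("describe", "metrics", "nullmodel", "fitdegree", "communities")


@dataclass
class RunConfig:
    """One pipeline run: either file inputs or a synthetic configuration."""

    edges: str | None = None          # processed edge-list CSV
    nodes: str | None = None          # node-list CSV
    raw_entries: str | None = None    # raw three-point survey CSV
    synthetic: SyntheticConfig | None = None
    out_dir: str = "results"
    years: tuple[int, ...] = STUDY_YEARS
    seed: int = 0
    ensemble_size: int = 1000
    n_boot: int = 1000
    swaps_per_link: int = DEFAULT_SWAPS_PER_LINK
    density_doubled: bool = False
    assortativity_convention: str = "directed-out-in"
    community_weighted: bool = False
    community_year: int | None = None  # default: most recent year
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        has_files = self.nodes is not None and (
            self.edges is not None or self.raw_entries is not None)
        if has_files == (self.synthetic is not None):
            raise ValueError("exactly one of (input files, synthetic config) "
                             "must be given")


def load_inputs(config: RunConfig) -> tuple[MovementTable, pd.DataFrame]:
    """Resolve the configured input source into (movement table, node list)."""
    if config.synthetic is not None:
        markets = generate_markets(config.synthetic)
        entries = generate_movements(config.synthetic, markets)
        table = split_survey_entries(entries, markets)
    else:
        markets = read_node_list(config.nodes)
        if config.raw_entries is not None:
            entries = read_raw_entries(config.raw_entries)
            table = split_survey_entries(entries, markets)
        else:
            table = read_edge_list(config.edges)
    return filter_movements(table, markets.index), markets


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the artifact paths written."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    table, markets = load_inputs(config)
    yearly = build_yearly_networks(table, config.years)
    overall = build_overall_network(table)

    if "describe" in config.stages:
        frames = []
        for dim in ("movement-type", "livestock", "transport",
                    "origin-country", "destination-country"):
            s = summarize_movements(table, dim).reset_index(names="category")
            s.insert(0, "dimension", dim)
            frames.append(s)
        path = out_dir / "table4_summary.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        artifacts["summary"] = path
        monthly = summarize_movements(table, "month-livestock")
        monthly.to_csv(out_dir / "monthly_livestock.csv")
        artifacts["monthly"] = out_dir / "monthly_livestock.csv"

    reports = {}
    if "metrics" in config.stages:
        for year, net in yearly.items():
            rep = metric_report(
                net, markets, density_doubled=config.density_doubled,
                assortativity_convention=config.assortativity_convention)
            if net.n >= 2 and net.l >= 1:
                try:
                    rep.propinquity_p = propinquity_test(net, markets).p_value
                except ValueError:
                    pass
            reports[year] = rep
        path = out_dir / "table5_metrics.csv"
        report_frame(reports).to_csv(path)
        artifacts["metrics"] = path

        comp_rows = {}
        for year, net in yearly.items():
            strong = connected_components(net, "strong")
            weak = connected_components(net, "weak")
            comp_rows[year] = {
                "gscc_size": strong[0] if strong else 0,
                "gscc_pct": 100.0 * strong[0] / net.n if net.n else np.nan,
                "gwcc_size": weak[0] if weak else 0,
                "gwcc_pct": 100.0 * weak[0] / net.n if net.n else np.nan,
            }
        path = out_dir / "table7_components.csv"
        pd.DataFrame(comp_rows).to_csv(path)
        artifacts["components"] = path

        path = out_dir / "table8_key_markets.csv"
        key_market_table(yearly, markets).to_csv(path, index=False)
        artifacts["key_markets"] = path

    if "nullmodel" in config.stages:
        if not reports:
            for year, net in yearly.items():
                reports[year] = metric_report(net, markets)
        z_frames = {}
        for year, net in yearly.items():
            if net.l < 2:
                logger.warning("skipping null model for %s: too few links", year)
                continue
            ensemble = generate_ensemble(net, size=config.ensemble_size,
                                         seed=config.seed,
                                         swaps_per_link=config.swaps_per_link)
            report = z_scores(reports[year].as_dict(), ensemble,
                              seed=config.seed)
            report.min_ensemble_propinquity_p = ensemble_propinquity(
                net, markets, size=config.ensemble_size, seed=config.seed,
                swaps_per_link=config.swaps_per_link)
            col = report.metrics["z"].copy()
            col["min_ensemble_propinquity_p"] = \
                report.min_ensemble_propinquity_p
            z_frames[year] = col
        path = out_dir / "table6_zscores.csv"
        pd.DataFrame(z_frames).to_csv(path)
        artifacts["zscores"] = path

    if "fitdegree" in config.stages:
        fits = {}
        for label, mode in (("movements", "movements"), ("links", "neighbors")):
            seq = degree_sequences(overall, mode=mode, direction="all")
            entry: dict = {"n": int(seq.values.size)}
            try:
                pl = fit_discrete_power_law(seq)
                pl.gof_p = gof_pvalue(seq, pl, n_boot=config.n_boot,
                                      seed=config.seed)
                entry["powerlaw"] = dataclasses.asdict(pl)
                ln = fit_lognormal(seq, pl.x_min)
                entry["lognormal"] = dataclasses.asdict(ln)
                entry["vuong"] = dataclasses.asdict(
                    vuong_compare(seq, pl, ln))
                ccdf_table(seq, pl, ln).to_csv(
                    out_dir / f"ccdf_{label}.csv", index=False)
            except ValueError as exc:
                entry["error"] = str(exc)
            fits[label] = entry
        path = out_dir / "degree_fit.json"
        path.write_text(json.dumps(fits, indent=2, default=float))
        artifacts["degree_fit"] = path

    if "communities" in config.stages:
        year = config.community_year or max(
            y for y, net in yearly.items() if net.n > 0)
        part = fast_greedy_communities(yearly[year],
                                       weighted=config.community_weighted)
        rows = [{"market": v, "country": markets.loc[v, "country"]
                 if v in markets.index else None, "community": c}
                for v, c in sorted(part.membership.items())]
        df = pd.DataFrame(rows)
        df.attrs["q"] = part.q
        path = out_dir / "communities.csv"
        df.to_csv(path, index=False)
        (out_dir / "communities_summary.json").write_text(json.dumps(
            {"year": year, "q": part.q, "n_communities": part.n_communities}))
        artifacts["communities"] = path

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "counters": table.counters.as_dict(),
        "config": {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                       else v)
                   for k, v in dataclasses.asdict(config).items()},
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(provenance, indent=2, default=str))
    artifacts["provenance"] = path
    return artifacts
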