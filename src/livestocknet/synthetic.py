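"""Seeded synthetic survey data with the structure the analysis assumes.

The generator emulates the raw survey shape (origin -> survey point ->
destination entries with monthly dates, four livestock types, three
transport modes and scaled head counts) and plants the statistical features
the pipeline is designed to detect:

* a hub-dominated, disassortative topology: a few hub markets attract a
  disproportionate share of connections from many low-degree markets, with
  hub-hub links kept below the degree-sequence expectation;
* spatial propinquity: endpoint choice decays exponentially with distance,
  so trading pairs are closer than non-trading ones, while the hubs sit at
  the geographic fringe of the market cloud (borders and coast), so a
  degree-preserving null shows no propinquity;
* directional Sahel-to-coast flows with long-range export corridors;
* a seasonal sheep peak in the two months before each Tabaski date;
* a configurable fraction of entries with a missing endpoint, to exercise
  the preprocessing filters.

Markets form corridor clusters around survey anchors inside a northern
production belt; countries are latitude bands, giving reproducible border
flags. Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from livestocknet.data_io import (
    MovementTable, split_survey_entries, filter_movements,
)

#: km per degree of longitude at the equator (spherical approximation)
_KM_PER_DEG = 111.32


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic survey-data generator.

    Defaults emulate the scale and composition of the 2013-2017 regional
    survey: ~980 raw entries per month over 56 months, yielding roughly 42k
    movements after splitting and filtering; a livestock mix dominated by
    cattle with a fifth sheep; transport dominated by vehicles; Tabaski in
    September/October with a sheep peak in the two months before it.
    """

    seed: int = 0
    n_markets: int = 260
    n_countries: int = 6
    bounding_box: tuple[float, float, float, float] = (5.0, 15.0, -6.0, 4.0)
    #: (lat_min, lat_max, lon_min, lon_max)
    #: production belt holding the interior collection markets, as fractions
    #: of the box (lat_lo, lat_hi, lon_lo, lon_hi): a compact Sahelian zone
    #: well north of the coastal consumption markets
    belt: tuple[float, float, float, float] = (0.55, 0.9, 0.2, 0.8)
    n_hubs: int = 12
    n_survey_points: int = 30
    hub_attachment_bias: float = 5.0
    #: fraction of destinations drawn as long-range corridor legs:
    #: hub-weighted with no distance decay (exports toward terminal markets)
    corridor_fraction: float = 0.15
    #: per-degree-latitude tilt making origins upstream (north) and
    #: destinations downstream (south) of the survey point, so flows run
    #: toward the coast and few links are reciprocated
    directional_bias: float = 0.6
    #: hub preference when sampling shipment endpoints; kept mild so that
    #: hub-hub links stay BELOW the degree-sequence expectation (trade runs
    #: periphery <-> hub, which is what makes the observed network more
    #: disassortative than its configuration-model null)
    endpoint_hub_bias: float = 2.0
    distance_decay_km: float = 100.0
    #: spread of the satellite markets around their survey anchor (the
    #: corridor-cluster structure of the surveyed trade basins)
    cluster_sd_km: float = 60.0
    monthly_volume: float = 980.0
    #: endpoint weight of the survey market itself (controls how often a
    #: shipment starts or ends at the collection point and is not split)
    survey_self_weight: float = 25.0
    livestock_mix: dict = field(default_factory=lambda: {
        "cattle": 0.737, "sheep": 0.204, "goat": 0.058, "donkey": 0.001})
    transport_mix: dict = field(default_factory=lambda: {
        "vehicle": 0.944, "foot": 0.044, "train": 0.012})
    period: tuple[str, str] = ("2013-01", "2017-08")
    tabaski_dates: tuple[str, ...] = ("2013-10", "2014-10", "2015-09",
                                      "2016-09", "2017-09")
    sheep_peak_multiplier: float = 3.0
    missing_endpoint_fraction: float = 0.04
    border_km: float = 50.0
    heads_log_mu: float = 3.0
    heads_log_sigma: float = 1.0

    def validate(self) -> None:
        lat0, lat1, lon0, lon1 = self.bounding_box
        if not (lat1 > lat0 and lon1 > lon0):
            raise ValueError("degenerate bounding box")
        if self.n_hubs >= self.n_markets:
            raise ValueError("n_hubs must be < n_markets")
        for mix in (self.livestock_mix, self.transport_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"probabilities must sum to 1: {mix}")


def generate_markets(config: SyntheticConfig) -> pd.DataFrame:
    """Synthetic node list, indexed by market code.

    Countries are latitude bands (the trade runs north-south, from a Sahelian
    production belt toward the coast, so corridors cross east-west borders).
    Survey anchors are hub markets — border crossings between belt and
    coast, plus coastal terminal markets — and interior collection markets
    inside the belt; the remaining markets are satellites clustered around
    the anchors (mostly the belt ones). The border flag marks markets
    within ``border_km`` of a country-band boundary.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(0,)))
    lat0, lat1, lon0, lon1 = config.bounding_box
    n = config.n_markets
    n_survey = min(config.n_survey_points, n)
    n_hubs = min(config.n_hubs, n_survey)
    band_width = (lat1 - lat0) / config.n_countries
    boundaries = lat0 + band_width * np.arange(1, config.n_countries)
    lat_span = lat1 - lat0

    # survey anchors: hubs first (border crossings between the production
    # belt and the coast, plus coastal terminal markets at the southern
    # edge), then interior collection markets inside the belt
    lon_span = lon1 - lon0
    b_lat_lo, b_lat_hi, b_lon_lo, b_lon_hi = config.belt
    a_lat = np.empty(n_survey)
    a_lon = rng.uniform(lon0, lon1, size=n_survey)
    n_border_hubs = (2 * n_hubs) // 3
    if boundaries.size:
        # the boundary nearest to the gap between belt and coast
        gap_lat = lat0 + 0.2 * lat_span
        border_line = boundaries[np.argmin(np.abs(boundaries - gap_lat))]
    else:
        border_line = lat0 + 0.3 * lat_span
    for i in range(n_border_hubs):
        a_lat[i] = border_line + rng.normal(0, 0.08)
    for i in range(n_border_hubs, n_hubs):
        a_lat[i] = lat0 + abs(rng.normal(0, 0.2))  # coastal terminals
    a_lat[n_hubs:] = lat0 + lat_span * rng.uniform(
        b_lat_lo, b_lat_hi, n_survey - n_hubs)
    a_lon[n_hubs:] = lon0 + lon_span * rng.uniform(
        b_lon_lo, b_lon_hi, n_survey - n_hubs)
    a_lat = np.clip(a_lat, lat0, lat1)

    # satellite markets cluster around the anchors (corridor structure);
    # production-belt anchors hold most satellites, terminal hubs few
    n_sat = n - n_survey
    anchor_w = np.ones(n_survey)
    anchor_w[:n_hubs] = 1.0 / 3.0
    anchor_of = rng.choice(n_survey, size=n_sat, p=anchor_w / anchor_w.sum())
    jitter = config.cluster_sd_km / _KM_PER_DEG
    s_lat = np.clip(a_lat[anchor_of] + rng.normal(0, jitter, n_sat),
                    lat0, lat1)
    s_lon = np.clip(a_lon[anchor_of] + rng.normal(0, jitter, n_sat),
                    lon0, lon1)

    lat = np.concatenate([a_lat, s_lat])
    lon = np.concatenate([a_lon, s_lon])
    order = rng.permutation(n)  # codes carry no positional information
    lat, lon = lat[order], lon[order]
    hubs = np.zeros(n, dtype=bool)
    survey = np.zeros(n, dtype=bool)
    hubs[np.flatnonzero(order < n_hubs)] = True
    survey[np.flatnonzero(order < n_survey)] = True
    codes = [f"M{i:03d}" for i in range(n)]

    band = np.minimum(((lat - lat0) // band_width).astype(int),
                      config.n_countries - 1)
    country = np.array([f"C{b}" for b in band])
    if boundaries.size:
        dist_to_border = np.min(np.abs(lat[:, None] - boundaries[None, :]),
                                axis=1) * _KM_PER_DEG
    else:
        dist_to_border = np.full(n, np.inf)  # single country: no borders

    border = dist_to_border <= config.border_km

    urban = rng.random(n) < 0.15
    urban |= hubs & (rng.random(n) < 0.7)

    df = pd.DataFrame({
        "code": codes,
        "name": codes,
        "country": country,
        "latitude": np.round(lat, 6),
        "longitude": np.round(lon, 6),
        "is_survey_point": survey,
        "border_within_50km": border,
        "is_urban": urban,
        "is_hub": hubs,
    }).set_index("code")
    return df


def _pair_distances_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    # equirectangular approximation: adequate for weighting endpoint choice
    mean_lat = np.radians(lat).mean()
    x = lon * _KM_PER_DEG * np.cos(mean_lat)
    y = lat * _KM_PER_DEG
    return np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])


def generate_movements(config: SyntheticConfig,
                       markets: pd.DataFrame) -> pd.DataFrame:
    """Raw survey entries (origin, survey, destination triplets).

    Survey points are chosen hub-biased (``hub_attachment_bias``). Each
    endpoint is sampled with probability proportional to
    ``endpoint_hub_bias**is_hub * exp(-distance / distance_decay_km)``
    relative to the survey point, tilted so origins lie upstream (north)
    and destinations downstream; a ``corridor_fraction`` of destinations is
    redrawn hub-weighted without distance decay (long-range exports). This
    plants propinquity, beyond-null disassortativity and directional flows
    at once. An endpoint can coincide with the survey point (such legs are
    not split downstream).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(1,)))
    lat = markets["latitude"].to_numpy(dtype=float)
    lon = markets["longitude"].to_numpy(dtype=float)
    codes = markets.index.to_numpy()
    is_hub = markets["is_hub"].to_numpy(dtype=bool) \
        if "is_hub" in markets.columns \
        else markets["is_survey_point"].to_numpy(dtype=bool)
    survey_idx = np.flatnonzero(markets["is_survey_point"].to_numpy(dtype=bool))
    if survey_idx.size == 0:
        raise ValueError("no survey points in the market table")

    dist = _pair_distances_km(lat, lon)
    # local endpoint weights per survey point, rows aligned with survey_idx
    end_w = np.where(is_hub, config.endpoint_hub_bias, 1.0)
    W = end_w[None, :] * np.exp(-dist[survey_idx] / config.distance_decay_km)
    # directional tilt: origins upstream (north), destinations downstream
    tilt = np.exp(config.directional_bias
                  * (lat[None, :] - lat[survey_idx, None]))
    W_origin = W * tilt
    W_dest = W / tilt
    for M in (W_origin, W_dest):
        M[np.arange(survey_idx.size), survey_idx] = config.survey_self_weight
        M /= M.sum(axis=1, keepdims=True)
    # long-range corridor endpoint weights (hub terminals, no decay)
    corridor_w = np.where(is_hub, config.hub_attachment_bias, 0.0)
    corridor_w = corridor_w / corridor_w.sum() if corridor_w.sum() else None
    hub_w = np.where(is_hub, config.hub_attachment_bias, 1.0)
    survey_w = hub_w[survey_idx] / hub_w[survey_idx].sum()

    months = pd.period_range(config.period[0], config.period[1], freq="M")
    peak_months = set()
    for t in config.tabaski_dates:
        tp = pd.Period(t, freq="M")
        peak_months.update((tp - 1, tp - 2))

    types = list(config.livestock_mix)
    base_mix = np.array([config.livestock_mix[t] for t in types])
    transports = list(config.transport_mix)
    transport_p = np.array([config.transport_mix[t] for t in transports])

    frames = []
    for month in months:
        n_entries = int(rng.poisson(config.monthly_volume))
        if n_entries == 0:
            continue
        mix = base_mix.copy()
        if month in peak_months:
            mix[types.index("sheep")] *= config.sheep_peak_multiplier
            mix = mix / mix.sum()
        livestock = rng.choice(types, size=n_entries, p=mix)
        transport = rng.choice(transports, size=n_entries, p=transport_p)
        s_local = rng.choice(survey_idx.size, size=n_entries, p=survey_w)
        origin = np.empty(n_entries, dtype=int)
        dest = np.empty(n_entries, dtype=int)
        for si in np.unique(s_local):
            rows = np.flatnonzero(s_local == si)
            origin[rows] = rng.choice(len(codes), size=rows.size,
                                      p=W_origin[si])
            dest[rows] = rng.choice(len(codes), size=rows.size, p=W_dest[si])
        if corridor_w is not None and config.corridor_fraction > 0:
            mask = rng.random(n_entries) < config.corridor_fraction
            if mask.any():
                dest[mask] = rng.choice(len(codes), size=int(mask.sum()),
                                        p=corridor_w)
        heads = np.round(rng.lognormal(config.heads_log_mu,
                                       config.heads_log_sigma,
                                       size=n_entries), 6)
        origin_codes = codes[origin].astype(object)
        dest_codes = codes[dest].astype(object)
        drop = rng.random(n_entries) < config.missing_endpoint_fraction
        side = rng.random(n_entries) < 0.5
        for i in np.flatnonzero(drop):
            if side[i]:
                origin_codes[i] = pd.NA
            else:
                dest_codes[i] = pd.NA
        frames.append(pd.DataFrame({
            "origin_market": origin_codes,
            "survey_market": codes[survey_idx[s_local]],
            "destination_market": dest_codes,
            "month": month,
            "livestock_type": livestock,
            "heads": heads,
            "transport": transport,
        }))
    if not frames:
        return pd.DataFrame(columns=["origin_market", "survey_market",
                                     "destination_market", "month",
                                     "livestock_type", "heads", "transport"])
    out = pd.concat(frames, ignore_index=True)
    out["month"] = pd.PeriodIndex(out["month"], freq="M")
    return out


def build_movement_table(config: SyntheticConfig
                         ) -> tuple[MovementTable, pd.DataFrame]:
    """Convenience: generate, split and filter in one call.

    Returns the filtered movement table and the market node list.
    """
    markets = generate_markets(config)
    entries = generate_movements(config, markets)
    table = split_survey_entries(entries, markets)
    table = filter_movements(table, markets.index)
    return table, markets


def write_fixture(entries: pd.DataFrame, markets: pd.DataFrame,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write raw-entry, edge-list and node-list CSVs in the survey dialect.

    The edge list is the split + filtered view of ``entries``, so both input
    paths of the reading layer are exercised by the same fixture.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    raw_path = out_dir / "raw_entries.csv"
    raw = entries.rename(columns={
        "origin_market": "from", "survey_market": "survey",
        "destination_market": "to", "month": "dmonth",
        "livestock_type": "type", "heads": "weight", "transport": "transp"})
    raw = raw.copy()
    raw["dmonth"] = raw["dmonth"].astype(str)
    raw.to_csv(raw_path, index=False)

    node_path = out_dir / "node_list.csv"
    nodes = markets.reset_index().rename(columns={
        "code": "name", "name": "label", "country": "cid",
        "latitude": "lat", "longitude": "lon", "is_survey_point": "survey",
        "border_within_50km": "border50km", "is_urban": "urban"})
    nodes.drop(columns=[c for c in ("is_hub",) if c in nodes.columns]) \
        .to_csv(node_path, index=False, float_format="%.6f")

    table = filter_movements(split_survey_entries(entries, markets),
                             markets.index)
    edge_path = out_dir / "edge_list.csv"
    edges = table.records.rename(columns={
        "from_market": "from", "to_market": "to", "from_country": "fromc",
        "to_country": "toc", "month": "dmonth", "livestock_type": "type",
        "heads": "weight", "transport": "transp", "international": "intl"})
    edges = edges.copy()
    edges["dmonth"] = edges["dmonth"].astype(str)
    edges.to_csv(edge_path, index=False, float_format="%.6f")
    return {"raw": raw_path, "nodes": node_path, "edges": edge_path}
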