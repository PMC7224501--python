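# livestocknet

Network analysis of regional livestock trade for veterinary epidemiology
and market-structure research. The package turns market-survey shipment
records — each entry a movement of cattle, sheep, goats or donkeys from an
origin market through a data-collection (survey) point to a destination —
into yearly directed weighted market networks, and characterises them the
way the field studies animal-mobility networks:

* **Preprocessing** — splitting each survey entry into up to two directed
  movements, excluding self-loops and incomplete or unmappable records,
  with provenance counters that account for every row.
* **Network construction** — one directed simple graph per year (and one
  overall), nodes = markets, links = ordered trading pairs weighted by
  movement counts and scaled animal volumes. Symbols: *n* markets, *m*
  shipments, *l* directed links.
* **Network statistics** — diameter (directed/undirected, finite geodesics),
  link density *l*/*n*(*n*−1), average link degree *l*/*n*, average
  shipments *m*/*n*, clustering, mean path length, degree assortativity
  (Pearson correlation of source out-degree and target in-degree over
  links), Freeman centralizations, GSCC/GWCC sizes, node-level volumes and
  degrees, and key-market rankings.
* **Propinquity** — do trading markets sit closer together than
  non-trading ones? Haversine distances for all unordered market pairs,
  compared between linked and unlinked pairs with a one-sided Mann-Whitney
  test (H1: unlinked distances are stochastically larger).
* **Configuration-model nulls** — degree-preserving double-edge-swap
  ensembles (no self-loops, no multi-edges, 10·*l* attempted swaps per
  replicate); observed metrics normalised as z = (obs − mean)/sd, and the
  minimum ensemble propinquity p-value reported per year.
* **Heavy-tailed degree fits** — discrete power-law maximum likelihood with
  KS-minimising x_min selection, semi-parametric bootstrap goodness of fit,
  discretised log-normal alternative, and the Vuong non-nested test.
* **Trade communities** — fast-greedy modularity maximisation on the
  undirected simplification, with modularity Q recomputed independently.
* **Synthetic survey generator** — a seeded generator that emulates the
  survey's structure (Sahelian production belt, border and coastal hub
  markets, distance-decayed local trade plus long-range export corridors,
  pre-Tabaski sheep peaks, missing endpoints), so the entire pipeline is
  testable without access to the original files.

## Worked example

Generate a synthetic survey fixture and analyse it end to end:

```sh
livestocknet simulate --seed 1 --out fixtures
livestocknet all --edges fixtures/edge_list.csv --nodes fixtures/node_list.csv \
    --ensemble-size 200 --n-boot 300 --seed 1 --out results
```

or from Python:

```python
from livestocknet import (SyntheticConfig, build_yearly_networks,
                          metric_report, propinquity_test)
from livestocknet.synthetic import build_movement_table

table, markets = build_movement_table(SyntheticConfig(seed=1))
print(len(table), table.counters.dropped_incomplete)
net = build_yearly_networks(table)[2013]
print(net.n, net.m, net.l)
print(round(metric_report(net, markets).degree_assortativity, 3))
print(propinquity_test(net, markets).p_value)
```

prints

```
45993 2200
260 9865 3543
-0.593
2.5710142130724483e-86
```

i.e. 45,993 movements were retained after splitting and filtering (2,200
legs dropped for a missing endpoint), the 2013 network connects 260 markets
with 9,865 shipments over 3,543 directed links, markets trade
disassortatively (hubs with peripheral markets, r ≈ −0.59), and trading
pairs are far closer together than non-trading ones (one-sided Mann-Whitney
p ≈ 3e−86).

The `all` run writes the report tables (`table4_summary.csv` …
`table8_key_markets.csv`, `degree_fit.json`, `communities.csv`) plus a
`provenance.json` that echoes counters, seed and configuration so a run can
be reproduced bit-identically.

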