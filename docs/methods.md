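# Methods

## From survey entries to movement records

Each raw survey entry records a shipment passing a data-collection point:
origin market → survey market → destination market, with a month, livestock
type, transport mode and a (scaled) head count. An entry is split into up to
two directed movements — origin→survey and survey→destination — and a leg is
suppressed only when its outer endpoint *equals* the survey point, so no
self-loop is ever created. A leg whose outer endpoint is missing is emitted
with the missing endpoint and removed by the subsequent incomplete filter;
ordering the pipeline as split → filter (rather than refusing to emit the
leg) makes every planted missing endpoint visible in the provenance
counters. Filtering then drops, in order: incomplete legs, legs whose
endpoint is not in the geolocated node list, and self-loops from
already-split input. The invariant `rows read (or created by splitting) =
retained + Σ dropped` is asserted after every filtering step.

Category labels are normalised case-insensitively to {cattle, goat, sheep,
donkey} and {vehicle, foot, train}. The international flag is always
recomputed as `from_country != to_country`; a conflicting flag in the input
is overridden and counted, since the country columns are the authoritative
source. Head counts are kept in the scaled units the data arrive in; no
attempt is made to invert the anonymising scaling, so all "volume" outputs
are relative.

## Networks and metrics

Movements aggregate into one directed simple graph per calendar year
2013–2017 and one overall graph; parallel movements merge into a single
link carrying `movement_count` and `animal_volume`. Nodes are only the
markets appearing as endpoints in that year. All topological metrics are
computed on the unweighted topology.

Conventions (chosen to match the common igraph defaults of the field's
toolchain, and validated against frozen reference values in the tests):

* **Geodesics.** Diameter and mean path length use finite shortest paths
  only; unreachable ordered pairs are excluded from numerator and
  denominator. The yearly networks are far from strongly connected, so this
  is the only way these statistics are finite.
* **Link density** is l/(n(n−1)); a divisor of 2n(n−1) is available as an
  option (`doubled=True`) for comparability with reports that use the
  doubled maximum.
* **Transitivity** defaults to the average of local clustering coefficients
  over nodes with degree ≥ 2 on the undirected simplification
  (`include_low_degree=True` averages over all nodes, counting degree-<2
  nodes as zero); the global 3×triangles/triples variant is always computed
  alongside, and the report stores both.
* **Degree assortativity** defaults to the Pearson correlation, over
  directed links, of source out-degree with target in-degree; an
  undirected-total-degree convention is provided as a fallback. Zero
  variance on either endpoint vector makes the statistic undefined.
* **Freeman centralization** divides Σᵢ(C_max − Cᵢ) by the star-graph
  maximum: 2(n−1)(n−2) for directed total degree, (n−1)² for in-/out-degree,
  (n−1)²(n−2) for directed betweenness, and (n−1)(n−2)/(2n−3) for
  normalised closeness on the undirected graph. Closeness centralization is
  undefined on disconnected graphs and reported as missing.
* Metrics that are mathematically undefined on a given network raise a
  typed signal (`UndefinedMetric`) and appear as missing values in report
  tables, never as silent zeros.
* Key-market rankings break ties lexicographically by market code so runs
  are deterministic.

## Propinquity

All n(n−1)/2 unordered market pairs are partitioned into *linked* (trade in
either direction — the hypothesis concerns whether any trade occurs) and
*unlinked*. Great-circle distances use the Haversine formula with the IUGG
mean Earth radius 6371.0088 km. The one-sided Mann-Whitney test (H1:
unlinked distances stochastically larger) uses exact enumeration when both
groups have ≤ 10 tie-free observations and the normal approximation with
continuity and tie correction otherwise; the survey-scale networks always
take the asymptotic path, where the reported p-values are far beyond the
reach of enumeration anyway.

## Configuration-model ensembles

The null model preserves every market's in- and out-degree and randomises
everything else: 10·l attempted double-edge swaps per replicate (the
`swaps_per_link` budget is configurable; larger values are safer for
mixing), with swaps that would create a self-loop or parallel link rejected
and redrawn. Degree preservation is exact by construction and asserted in
tests on every replicate. Replicate i draws from an independent,
order-insensitive substream of the master seed, so ensembles are
reproducible regardless of execution order.

Per replicate the ensemble records only the metrics not fixed by degree
preservation: both diameters, average-local transitivity, mean path length,
degree assortativity and betweenness centralization. z-scores use the
sample (n−1) standard deviation; a zero-variance metric is flagged rather
than scored. The propinquity test is re-run on every replicate with the
original coordinates and the minimum p over the ensemble is reported — a
minimum near 1 means no randomised network reproduces the observed spatial
signal.

## Heavy-tailed degree fits

Degrees are counts, so all likelihoods are discrete. For each candidate
cutoff x_min (every distinct observed value with a tail of ≥ 8
observations), the power-law exponent is the Hurwitz-zeta-normalised
maximum-likelihood estimate, and the chosen x_min minimises the KS distance
between the empirical tail CDF and the fitted model. Goodness of fit is a
semi-parametric bootstrap: each replicate resamples the body empirically,
draws the tail from the fitted model, refits everything (including cutoff
selection) and records its KS distance; p is the fraction of replicates at
least as discrepant as the data, with p > 0.1 read as plausible. The
log-normal alternative is a discretised (cell-probability) log-normal
truncated at the cutoff, fitted by Nelder-Mead. The Vuong statistic is the
per-point log-likelihood-ratio sum normalised by its standard deviation,
with a two-sided normal p; the comparison is declared indeterminate above
p = 0.1. Power-law bootstrap draws use the standard continuous-inverse
rounding approximation; the tests cross-check it against an exact
inverse-CDF table sampler.

## Communities

Directed links collapse to an undirected simple graph (reciprocal pairs
merged, counts summed) before fast-greedy agglomerative modularity
maximisation; the partition at the maximum of Q along the merge path is
returned. Detection is unweighted by default with movement counts available
as weights. The returned Q is recomputed independently from the membership
(and again from a hand formula in the tests). Community detection defaults
to the most recent year.

## The synthetic study conditions

The generator emulates the structure of the 2013–2017 regional survey, and
its defaults are the package's study conditions:

* **Geography.** A 10°×10° box spanning a Sahel-to-coast gradient.
  Countries are latitude bands (six by default), because the trade runs
  north–south and crosses east–west borders; border flags mark markets
  within 50 km of a band boundary. Markets form corridor clusters: 30
  survey anchors (spread over a compact northern production belt) plus
  satellites scattered ~60 km around them. Twelve anchors are hubs — border
  crossings on the boundary between belt and coast, and coastal terminal
  markets — placed at the southern fringe of the market cloud, as the real
  assembly and consumption hubs are.
* **Flows.** Each entry picks a survey point (hub-biased 5:1), an origin
  and a destination. Endpoints are sampled with probability ∝
  (endpoint hub bias)^is-hub × exp(−distance/100 km), tilted so origins lie
  upstream (north) and destinations downstream (south); 15% of destinations
  are long-range corridor exports drawn hub-weighted without distance
  decay. The endpoint hub bias is deliberately mild (2): hub degree comes
  from survey placement and corridor flows, while hub-hub links stay below
  the degree-sequence expectation. This combination plants the three
  higher-order signals the analysis is designed to detect — propinquity
  (local collection links are short), excess disassortativity (periphery↔hub
  trade), and an *anti*-propinquital configuration null (degree mass sits at
  the spatial fringe, so rewired links are long-range).
* **Composition.** ~980 entries/month over Jan 2013–Aug 2017, calibrated so
  ~42,000 movements survive filtering; livestock mix 73.7% cattle / 20.4%
  sheep / 5.8% goat / 0.1% donkey and transport mix 94.4% vehicle / 4.4%
  foot / 1.2% train, matching the survey's published composition; sheep
  share tripled in the two months before each Tabaski date (Sept/Oct,
  drifting earlier year by year); head counts log-normal(μ=3, σ=1) in
  arbitrary scaled units; 4% of entries get a missing endpoint to exercise
  the filters.

Everything is deterministic under the configured seed, including file
output (fixed-precision CSV).

**What the generator does not emulate.** Real road networks and actual
West-African geography; the survey's year-to-year changes in collection
sites; its very high link reuse (the synthetic networks spread shipments
over more distinct pairs, so yearly l is larger and average shipments per
link smaller than in the survey); its low clustering (hub-core cliquishness
makes synthetic average-local transitivity high, ~0.7–0.9); and its weakly
reciprocated flows (synthetic giant strongly-connected components are much
larger). Tests passing on synthetic data therefore validate the pipeline's
correctness and its ability to detect planted structure — not any claim
about the original survey's specific metric values, which require the
original files.

## Problem sizes

Defaults are ensemble size 1000 and 1000 bootstraps. The acceptance script
runs 200 ensemble replicates and 300 bootstraps per fit — the package's
standard reduced setting for quick reproduction runs — and the test suite
uses smaller ensembles still (25–200) on the same study conditions.

## Known limitations

* The propinquity test treats pairs as independent observations; with
  n(n−1)/2 pairs the asymptotic p-values are extremely small and should be
  read as orderings, not calibrated probabilities.
* The rewiring chain is run with a fixed attempt budget (10·l) rather than
  a mixing diagnostic; dense hub cores retain some unavoidable edge overlap
  with the observed network (the simple-graph constraint forces it).
* Discrete power-law bootstrap draws use the rounding approximation, which
  is slightly conservative for small x_min.
* The log-normal fit can sit on a likelihood plateau (μ drifting very
  negative with σ² growing) when the tail is short; the Vuong comparison is
  still well-defined there, but the parameters themselves should not be
  over-interpreted.
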