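# Methods

## Scope and model

`nfkbkit` treats a signaling system as three layers: curated *seed sets* of
proteins implicated in the activation of a transcription factor, the
*interactomes* obtained by enriching those sets with experimentally
supported physical interactions from a PPI edge table, and a *downstream
set* of proteins whose genes the factor regulates. The analyses are
deliberately structural, not dynamical: undirected graphs, exact set
algebra, and exact count-based tests. No edge weights, directionality or
confidence scores are modeled, and no kinetic or Boolean dynamics are
attempted.

## Identifier handling

The canonical namespace is the identifier as given (UniProt entry name or
accession), stripped and uppercased. The toolkit does not resolve
cross-database synonyms: identifier conversion is treated as a snapshot
input produced upstream (converter exports), because online resolution is
neither deterministic nor reproducible. Canonicalization is idempotent and
applied at every ingestion point, so a protein can never appear twice under
case or whitespace variants. Duplicate edge lines — common when several
source databases report the same pair — collapse into one record with
merged evidence labels; the reported interaction count is the number of
distinct unordered pairs, self-pairs included.

## Interactome construction rules

*Direct* rule: node set = core members present in the PPI table plus all
their interaction partners; edge set = all PPI edges with both endpoints in
that node set. Including neighbor–neighbor edges (the full induced
subgraph) matches how interaction-retrieval plugins materialize
first-neighborhood queries; an edge count far exceeding the edges incident
to a handful of core hubs is only reproducible under this reading. The
stricter star policy (core-incident edges only) remains available via
`edges="star"`.

*Induced* rule: node set = seeds found in the PPI table (absentees are
listed in the network's provenance); edge set = PPI edges internal to the
seed list.

Union takes node- and edge-set unions; the core network restricts the
union's edges to the intersection of node sets. Component summaries are
computed over non-self-loop edges; a node whose only edge is a self-loop is
isolated. Equal-size largest components tie-break on the lexicographically
smallest member, and all output orderings are sorted, so every run is
deterministic.

## Topology conventions

Self-loops are excluded from every connectivity statistic (they remain in
the interaction count only). Density is the mean distinct-neighbor count
divided by n−1. Degree centralization follows the
(n/(n−2))·(d_max/(n−1) − density) convention used by the Cytoscape-lineage
network analyzers, clamped to [0,1]; a Freeman-style normalization is
available behind a flag and agrees on stars and regular graphs.
Betweenness is unweighted Brandes betweenness (via networkx) normalized by
2/((n−1)(n−2)) using the *whole network's* n even when components are
disconnected — a single ranking table across a fragmented interactome
requires one common scale. A `per_component` option renormalizes within
components for users who prefer the local convention. Metric values are
stored at full precision; rounding happens only in report output
(half-even, the platform default; reported tables use 1–3 decimals and
betweenness 8).

## Over-representation testing

The test is the exact one-sided hypergeometric upper tail
P(X ≥ hits | M, K, N), computed with `scipy.stats.hypergeom.sf`. The
background defaults to the union of all pathway members in the annotation,
and is always an explicit, logged choice: enrichment suites differ chiefly
in their hidden backgrounds, so the toolkit refuses to have one. Study-set
members outside the background are excluded from the contingency (logged),
never silently counted. Benjamini–Hochberg q-values are computed over all
tested pathways before any filtering; the significance filter itself is raw
p < α (default 0.05) because coverage-style reports conventionally filter
on raw p, with q available in every row. A `decimal_comma` rendering option
reproduces European-style `17,07` percentage formatting byte-for-byte for
regression fixtures.

## Bow-tie and feedback

Feedback proteins are the intersection of the upstream interactome's node
set with the downstream target set — a deterministic set operation, not an
inference. The feedback *fraction* is reported against a labeled
denominator policy: `downstream_checked` (targets checked against the PPI
source; the default), `downstream_mapped`, or `downstream_all`, because the
natural denominators (targets found in the PPI database, mapped protein
IDs, raw gene list) genuinely differ and the choice changes the headline
percentage (49/384 = 12.8% vs 49/410 = 12.0% vs 49/426 = 11.5%). In the
bow-tie partition, knob membership takes precedence: a family member that
is also a downstream target stays in the knob and is flagged
`knob_feedback`, which keeps the four classes a true partition while still
exposing the self-regulated subunits.

## Synthetic studies

The generator's defaults reproduce the dimensions of the NF-κB study the
toolkit was built around: a 2,000-protein PPI universe grown by
preferential attachment (m = 3) so that hubs exist (no degree-exponent
claim is made), 8% independent self-loop probability, three seed sets of
377/210/141 proteins realizing Venn regions (307, 140, 85, 34, 20, 20, 16)
— union 622, triple intersection 16, which also hosts the 5-member knob —
a 20-pathway annotation with sizes uniform on [40, 300] containing one
pathway enriched in the upstream union at odds ratio 8, and a 384-member
downstream set sharing exactly 49 proteins with the upstream union. The
published pairwise overlap percentages are mutually inconsistent with any
single denominator given the printed set sizes (inclusion–exclusion over a
622-member union forces the pairwise-region total to 74, not the ≈134 a
grand-union back-calculation yields), so the planted regions reproduce the
set sizes, union, and triple intersection exactly and let the pairwise
percentages fall where they must.

Planted pathways fix the inside/outside-target membership odds at the
requested odds ratio with the expected size matching the drawn size
(Bernoulli sampling; the root `p0` is solved numerically with Brent's
method). Fresh downstream identifiers use a reserved `SYN%05d` namespace so
they can never collide with real accessions. All sampling flows from one
`numpy.random.Generator`; a fixed seed yields byte-identical study files.

What the generator does *not* emulate: literature-curation noise, database
evidence codes, identifier-mapping failures, or the correlation between a
protein's degree and its curation probability. Passing end-to-end tests
therefore demonstrate that the pipeline's algebra and statistics are
correct under known structure, not that any particular biological claim
holds on real data.

## Calibration and validation fixtures

The null calibration of the enrichment test draws, per replicate, a fresh
pathway size uniform on [40, 300] along with fresh random study and pathway
sets (universe 2,000, study set 200). Varying the pathway size across
replicates averages the achieved level of the discrete hypergeometric test
over many support grids; at any single fixed size the test's conservatism
(achieved level strictly below nominal, sometimes by half) would be the
dominant signal rather than the implementation's correctness. The observed
false-positive rate is required to sit within 3 standard errors of 0.05
over 1,000 replicates.

Centrality statistics are validated against brute-force oracles —
betweenness by exhaustive simple-path enumeration, density and
centralization directly from the degree sequence — on 500 random graphs of
up to 8 nodes; hypergeometric p-values against complete enumeration of all
draws for backgrounds up to 12. End-to-end recovery (exact Venn counts,
exact feedback members, planted pathway ranked first at α = 0.05 in ≥95%
of runs) is measured over 200 seeded studies at the default dimensions.

## Degenerate inputs and numerical notes

Density requires n ≥ 2 and centralization n ≥ 3 (errors below that);
betweenness on n < 3 returns zeros with a warning. Empty seed files, empty
GMT lines and inconsistent contingency counts raise typed errors naming
the offending file/line or counts. Disconnected pairs contribute nothing to
betweenness. An empty core intersection is a valid (warned) empty network.
Hypergeometric tails are computed in scipy's log-space implementation; the
test suite requires agreement with exact rational enumeration to 1e-12
relative.

## Replication of the published study

Rebuilding the published networks (377/4,119-edge direct interactome,
622/6,115 union, 16/89 core, the 49-member feedback set, the top-ranked
subunit's betweenness) requires the study's deposited supplementary exports
(PPI snapshot and identifier lists), which are distributed as
spreadsheet/session archives and are not bundled here. The replication
harness in `tests/test_acceptance.py` runs whenever those exports are
placed under `data/supplementary/`; without them it reports the missing
inputs as a failure rather than silently passing. Whether the published
interaction totals collapse duplicate per-database entries is not
documented; this toolkit reports distinct-pair counts and logs raw line
counts so the two can be compared when the exports are present.
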