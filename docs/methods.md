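# Methods

## The metric-space model

An undirected PIN is modelled as a metric space under hop-count
shortest-path distance d(u, v).  The analysis assumes a simple graph
(readers drop self-loops and collapse duplicate/reversed edges, with
logged counts) over exact gene-symbol node IDs — no case folding or alias
resolution, since any symbol normalisation would silently change zone
counts.  Edges are unweighted and untyped; SIF relation labels are
ignored.

- **Eccentricity** ecc(v) = max hop distance from v to any node of its
  connected component.
- **Centre** = the set of eccentricity minimisers of the largest connected
  component; the minimum is the radius.  All tied minimisers are returned
  — real networks have been observed with single centres, but the method
  must not assume one.  Degree plays no role in centre finding.
- **Zone k** = nodes at distance exactly k from the centre (minimum over
  centres when tied), computed by multi-source BFS.  Zone 0 is the centre
  itself, reported separately and excluded from zone tables and tests.
- Nodes outside the centre's component have no defined distance to it;
  they are reported as *unreachable*, not zoned.  This is the only reading
  under which "zones around the centre" covers the analysis set; how the
  original network studies handled disconnected fragments is unstated.

Every decomposition is checkable via `ZoneDecomposition.validate`: zone-k
nodes (k ≥ 1) must have a zone-(k−1) neighbour, zones plus unreachable
nodes partition the node set, the largest zone index equals the radius,
and radius ≤ diameter (≤ 2·radius for a single centre; with a tied centre
set the decomposition radius — the eccentricity of the centre *set* — can
legitimately be smaller than the graph radius, so the upper bound is only
asserted for single centres).

Per-zone metrics (node count, average/min/max degree, quill count, where a
quill is a degree-1 node) use degrees in the **full** network, not the
zone-induced subgraph.  Eccentricities are computed with sparse-matrix BFS
(scipy `csgraph`), which keeps a ~5000-node network under ten seconds on
one core.

## Percentages and rounding

Distribution tables report one decimal, rounded half away from zero — a
single fixed convention.  The published tables this package's arithmetic
checks derive from mix conventions (some cells match rounding, others
truncation), so reproduction targets are restricted to cells where the
conventions agree.

Two percentage bases exist and are explicit in the API: `basis="zone"`
(share of a zone annotated — essential/disease/drug-target style tables)
and `basis="set"` (distribution of one gene set across zones, rows summing
to ~100% — consistent-expression style tables).  A distribution table's
"Average" row is the unweighted mean of the per-set percentage rows, i.e.
it averages the already-rounded per-set values, matching how such rows are
printed.

The consistent-expression filter keeps a gene iff it is called present in
≥ threshold (default 0.99) of a source's samples.  The boundary is
inclusive ("at least"); source texts also write "more than", and the
inclusive reading was chosen and is flagged here rather than silently
resolved.  Gene→protein mapping is identity (expression as a proxy for
protein presence).

## Statistics

**Two-proportion z-test.**  The pooled statistic
z = (p₁ − p₂)/√(p̂(1−p̂)(1/n₁ + 1/n₂)) with p̂ the pooled proportion, and
a two-sided normal p-value at α = 0.01 by default.  A one-sided mode is
available because the motivating hypothesis (central zones carry higher
proportions) is directional.  No continuity correction is applied.  When
p̂ ∈ {0, 1} the variance is zero and both sample proportions are
necessarily equal; the test is defined as z = 0, p = 1.  Pairwise zone
comparisons run over all unordered pairs or adjacent pairs only (both
offered, since which pairs the original analyses tested is unstated);
per-pair significance is the default, with optional Bonferroni across
pairs.  An exhaustive sweep of all 2×2 tables with margins ≤ 50
(1 755 625 tables) shows 97.1% significance agreement with Fisher's exact
test at α = 0.01; the 50 198 disagreements are borderline tables where the
z-test is anticonservative in all but 72, and the set is frozen in the
test suite as a stability check.  Notably, on the published essential-
protein counts the adjacent pairs (zone 3, zone 4) and (zone 4, zone 5)
do **not** separate at α = 0.01 (z = 1.28 and −0.03; Fisher agrees),
although zones 1–2 and 2–3 separate overwhelmingly.

**Over-representation.**  Upper-tail hypergeometric
P(X ≥ overlap) with population = universe, successes = pathway ∩ universe,
draws = zone set, Bonferroni-corrected over the pathways tested (empty
intersections retained with p = 1 and still counted).  The universe
defaults to the network's node set — the sampling frame actually analysed
— rather than the genome; pathway collections are user-supplied GMT files.
This in-package test replaces an external web-service enricher; it makes
no attempt to replicate that service's pathway database or exact p-values.

## The synthetic generator

`generate_core_periphery` plants a centre wired to every zone-1 node and
grows shells outward: each zone-k node gets exactly one guaranteed edge to
a uniform zone-(k−1) node, plus intra-zone and adjacent-zone edges at
per-zone probabilities decaying outward, plus degree-1 quills hung off the
previous shell.  Because every edge stays within a shell or crosses to an
adjacent one, the planted zone index equals the true BFS distance exactly.
Optional uniform noise edges break that guarantee in one direction only:
shortcuts shrink distances, so computed zone ≤ planted zone, which the
tests assert.

Centre recoverability is engineered, not hoped for: an **anchor chain**
(a path centre–a₁–…–a_K, one node per zone, wired to nothing else) pins
ecc(centre) = K while every other node has eccentricity ≥ K + 1, because
any path from a non-spine node to the spine tip must pass through the
centre.  The planted centre is therefore the unique eccentricity minimiser
for every seed, including noise presets (noise edges never touch the
spine).  Without the anchor chain, ties for the centre appeared in roughly
one seed in six at this scale.

The shipped `hfpin_like` preset (~500 nodes, 5 zones, sizes 40/210/175/15/5
plus 50 quills and the anchor chain) reproduces the qualitative structure
of the real networks: a single centre, average degree decaying outward,
~93% of nodes within distance 3 of the centre, and quill-dominated outer
zones.  The scale keeps the full test suite around ten seconds; a ~5000-
node `hfpin_like_large` preset is provided but not exercised by default.
What the generator does **not** emulate: the real networks' degree
distribution, clustering, specific zone sizes or any biological edge
semantics — passing recovery tests shows the algorithms are correct on
networks with known structure, not that real PINs have that structure.

Zone-biased annotations include each zoned node independently with its
zone's prevalence (defaults used in tests: 0.4/0.2/0.1 for zones 1–3,
emulating the monotone decay of essential-protein proportions); presence
matrices are i.i.d. Bernoulli calls per gene.  All generators are
bit-reproducible from a single integer seed.

Recovery of planted prevalences is asserted within 3 binomial standard
errors per zone with draws pooled across 20 seeds; pooling is used because
a per-seed, per-zone 3-SE bound over 60 simultaneous checks would fail
~15% of honest runs by chance alone.

## Pipeline

`run_full_analysis` validates every input before computing anything, then
writes zone assignments, the zone-metrics table, per-annotation
distributions with pairwise tests, set-basis expression distributions with
an average row, per-zone enrichment, optional KEGG Mapper colour files,
and a manifest (inputs, parameters, seed, package version, SHA-256 of
every output).  Outputs are sorted and carry no timestamps, so identical
config + seed ⇒ byte-identical bundles, and the manifest alone suffices to
re-run (`rerun_from_manifest`).  All randomness derives from the single
top-level seed via per-stage `SeedSequence` spawning, so adding a stage
does not perturb earlier ones.  Any stage failure aborts with a
stage-named error.

## Known limitations

- Replicating the published full-network tables (centre MAPK14, 9 zones,
  diameter 13 for the HFPIN, etc.) requires the original network files,
  which are consumed as user-supplied inputs and not redistributed; only
  the printed-count arithmetic and test statistics are recomputed here.
- The centre/zone machinery is exact but O(n·m) for eccentricities;
  networks beyond ~10⁵ edges will want the BFS restricted or sampled.
- Published table cells whose printed percentages are internally
  inconsistent with their own counts are excluded from reproduction
  checks rather than adjudicated.
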