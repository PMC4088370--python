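# pinzones

Metric-space zone analysis of protein interaction networks (PINs).

## The problem

Human PINs show a core–periphery structure: a small, densely connected
kernel of proteins surrounded by increasingly sparse shells ending in
degree-1 "quills".  Treating an undirected PIN as a metric space under
hop-count shortest-path distance *d(u, v)* makes this precise.  The
**topological centre** is the protein (or proteins) minimising the
eccentricity ecc(*v*) = max<sub>*u*</sub> *d(v, u)* — deliberately *not*
the highest-degree hub — and **zone k** is the set of proteins at distance
exactly *k* from the centre.  Zones turn out to be biologically meaningful
strata: the innermost zones of the human functional PIN (HFPIN) and the
human signalling network (HSN) are strongly enriched for essential,
disease-associated and approved drug-target proteins, which makes zone
membership a useful prioritisation signal in disease-gene and drug-target
studies.

`pinzones` implements this analysis for systems biologists as a reusable
pipeline:

- **metric space** — BFS distances, eccentricity, centre(s), radius,
  diameter, zone partition, and per-zone graph metrics (size, average /
  min / max degree, quill count);
- **zone annotation** — map gene sets (GMT) or consistent-expression gene
  sets derived from binary presence/absence matrices onto zones, with
  count/percentage distribution tables under both percentage conventions
  (fraction of a zone vs distribution of a set across zones);
- **zone statistics** — the pooled two-proportion z-test
  *z* = (*p*₁ − *p*₂) / √( *p̂*(1 − *p̂*)(1/*n*₁ + 1/*n*₂) ) for
  between-zone comparisons (α = 0.01 default), and upper-tail
  hypergeometric over-representation with Bonferroni correction;
- **synthetic data** — a planted core–periphery generator with recorded
  ground truth, so every stage is testable without external downloads;
- **I/O** — TSV/SIF edge lists, GMT gene sets, presence matrices,
  non-redundant network merging, and KEGG Mapper colour-file export
  (zone 1: red, 2: orange, 3: yellow, 4: green).

## Worked example

Generate the shipped ~500-node core–periphery preset and analyse it:

```sh
pinzones simulate --seed 0 --outdir demo
# wrote 501 nodes, 1581 edges to demo
pinzones metrics demo/network.tsv --out demo/metrics.tsv
```

```
      n_nodes  avg_degree  min_degree  max_degree  n_quills
zone
1          41        13.0           2          24         0
2         211         7.9           1          15         1
3         211         4.1           1          13        42
4          26         1.8           1           5        14
5          11         1.0           1           1        11
```

The decomposition recovers the planted centre with radius 5 and diameter
10; average degree decays outward and the two outer zones consist almost
entirely of quills — the qualitative shape of the real human PINs, where
~92–95% of proteins lie within distance 3 of the centre.  The zone map in
`demo/planted_truth.tsv` (ground truth) matches the computed
`pinzones decompose` output exactly.

Testing whether zone 1 carries a higher essential-protein proportion than
zone 2, using the published HFPIN counts (161/374 vs 1002/4610):

```python
from pinzones import two_proportion_z
r = two_proportion_z(161, 374, 1002, 4610)
print(f"z = {r.z:.2f}, p = {r.p_value:.2e}")   # z = 9.37, p = 7.11e-21
```

A whole run (decomposition, distribution tables, pairwise tests,
enrichment, KEGG colour files, manifest) is driven by a YAML config:
`pinzones run-all config.yaml`.  Identical config and seed give
byte-identical bundles.

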