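"""Statistics for between-zone comparisons.

The workhorse is the pooled two-proportion z-test of H0: p1 = p2,

    z = (p1 - p2) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)),
    p_hat = (x1 + x2) / (n1 + n2),

with a two-sided normal p-value by default (a one-sided mode is available
since the motivating hypothesis — central zones carry higher proportions
than peripheral ones — is directional).  No continuity correction is
applied; Fisher's exact test is available as a cross-check.

Over-representation of a pathway in a zone is tested with the upper-tail
hypergeometric (population = analysis universe, successes = pathway members
in the universe, draws = zone members), Bonferroni-corrected over the
pathways tested.  The universe defaults to the network's node set — the
sampling frame actually analysed — rather than the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from pinzones.metric_space import ZoneDecomposition
from pinzones.network_io import AnnotationSet
from pinzones.zone_annotation import ZoneDistributionReport

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class ProportionTestResult:
    """Pooled two-proportion z-test result for one pair of samples."""

    count1: int
    n1: int
    count2: int
    n2: int
    z: float
    p_value: float
    alpha: float
    label1: str = "sample1"
    label2: str = "sample2"
    alternative: str = "two-sided"

    @property
    def p1(self) -> float:
        return self.count1 / self.n1

    @property
    def p2(self) -> float:
        return self.count2 / self.n2

    @property
    def pooled_p(self) -> float:
        return (self.count1 + self.count2) / (self.n1 + self.n2)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one pathway in one gene set."""

    pathway: str
    overlap: int
    set_size: int
    pathway_size: int
    universe_size: int
    p_raw: float
    p_corrected: float

    @property
    def proportion(self) -> float:
        return self.overlap / self.set_size if self.set_size else 0.0

    def significant(self, alpha: float = DEFAULT_ALPHA) -> bool:
        return self.p_corrected < alpha


def two_proportion_z(
    count1: int,
    n1: int,
    count2: int,
    n2: int,
    alpha: float = DEFAULT_ALPHA,
    alternative: str = "two-sided",
    label1: str = "sample1",
    label2: str = "sample2",
) -> ProportionTestResult:
    """Pooled two-proportion z-test of H0: p1 = p2.

    ``alternative`` is ``"two-sided"`` (default), ``"larger"`` (H1: p1 > p2)
    or ``"smaller"``.  When the pooled proportion is 0 or 1 both sample
    proportions are necessarily equal, the variance is zero and the test is
    degenerate: z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not 0 <= count1 <= n1 or not 0 <= count2 <= n2:
        raise ValueError("counts must lie in [0, n]")
    if alternative not in ("two-sided", "larger", "smaller"):
        raise ValueError(f"unknown alternative {alternative!r}")
    p1, p2 = count1 / n1, count2 / n2
    pooled = (count1 + count2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        z = 0.0  # zero pooled variance forces p1 == p2
    else:
        se = (pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)) ** 0.5
        z = (p1 - p2) / se
    if alternative == "two-sided":
        p_value = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "larger":
        p_value = float(stats.norm.sf(z))
    else:
        p_value = float(stats.norm.cdf(z))
    return ProportionTestResult(
        count1=count1,
        n1=n1,
        count2=count2,
        n2=n2,
        z=float(z),
        p_value=min(float(p_value), 1.0),
        alpha=alpha,
        label1=label1,
        label2=label2,
        alternative=alternative,
    )


def fisher_exact_p(count1: int, n1: int, count2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for the same 2x2 table (cross-check)."""
    table = [[count1, n1 - count1], [count2, n2 - count2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pairwise_zone_tests(
    report: ZoneDistributionReport,
    alpha: float = DEFAULT_ALPHA,
    pairs: str = "all",
    bonferroni: bool = False,
    alternative: str = "two-sided",
) -> list[ProportionTestResult]:
    """Two-proportion z-tests between zones of one distribution report.

    ``pairs`` is ``"all"`` (every unordered zone pair) or ``"adjacent"``
    (consecutive zone indices only).  Zones of size 0 are skipped with a
    warning; zone 0 (the centre row) is excluded — a one- or two-protein
    "sample" is not a proportion.  ``bonferroni`` corrects the p-values for
    the number of pairs tested (off by default: the convention here is
    per-pair significance).
    """
    if report.basis != "zone":
        raise ValueError("pairwise zone tests need zone-size based proportions")
    zones = []
    for k in sorted(report.zone_sizes):
        if k == 0:
            continue
        if report.zone_sizes[k] == 0:
            logger.warning("zone %d has size 0; skipped", k)
            continue
        zones.append(k)
    if len(zones) < 2:
        raise ValueError("need at least two non-empty zones to compare")
    if pairs == "all":
        zone_pairs = list(combinations(zones, 2))
    elif pairs == "adjacent":
        zone_pairs = [(a, b) for a, b in combinations(zones, 2) if b == a + 1]
    else:
        raise ValueError(f"unknown pair selection {pairs!r}")
    results = []
    for a, b in zone_pairs:
        res = two_proportion_z(
            report.counts.get(a, 0),
            report.zone_sizes[a],
            report.counts.get(b, 0),
            report.zone_sizes[b],
            alpha=alpha,
            alternative=alternative,
            label1=f"zone {a}",
            label2=f"zone {b}",
        )
        if bonferroni:
            res = ProportionTestResult(
                **{**res.__dict__, "p_value": min(1.0, res.p_value * len(zone_pairs))}
            )
        results.append(res)
    return results


def hypergeometric_enrichment(
    zone_members: Iterable[str],
    pathways: Sequence[AnnotationSet],
    universe: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation with Bonferroni correction.

    For each pathway, raw p = P(X >= overlap) with population |universe|,
    successes |pathway ∩ universe|, draws |zone_members|.  Pathways with an
    empty intersection are retained with p = 1 and still count toward the
    Bonferroni factor.  Results are sorted by corrected p, then name.
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("enrichment universe is empty")
    members = frozenset(zone_members)
    if not members <= universe_set:
        raise ValueError("zone members must be a subset of the universe")
    n_tests = len(pathways)
    results = []
    for pathway in pathways:
        in_universe = pathway.members & universe_set
        overlap = len(in_universe & members)
        if overlap == 0:
            p_raw = 1.0  # upper tail from 0 covers the whole distribution
        else:
            p_raw = float(
                stats.hypergeom.sf(
                    overlap - 1, len(universe_set), len(in_universe), len(members)
                )
            )
        results.append(
            EnrichmentResult(
                pathway=pathway.name,
                overlap=overlap,
                set_size=len(members),
                pathway_size=len(in_universe),
                universe_size=len(universe_set),
                p_raw=p_raw,
                p_corrected=min(1.0, p_raw * n_tests),
            )
        )
    return sorted(results, key=lambda r: (r.p_corrected, r.p_raw, r.pathway))


def pathway_zone_proportions(
    decomposition: ZoneDecomposition,
    pathway: AnnotationSet,
) -> dict[int, float]:
    """Fraction of each zone's nodes (zones >= 1) belonging to the pathway."""
    out = {}
    for k, nodes in decomposition.zones().items():
        out[k] = len(nodes & pathway.members) / len(nodes)
    return out


def tests_to_frame(results: Sequence[ProportionTestResult]) -> pd.DataFrame:
    """Tabulate test results for TSV export."""
    return pd.DataFrame(
        {
            "group1": [r.label1 for r in results],
            "group2": [r.label2 for r in results],
            "count1": [r.count1 for r in results],
            "n1": [r.n1 for r in results],
            "count2": [r.count2 for r in results],
            "n2": [r.n2 for r in results],
            "z": [r.z for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "pathway_size": [r.pathway_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "proportion": [r.proportion for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_corrected": [r.p_corrected for r in results],
        }
    )
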