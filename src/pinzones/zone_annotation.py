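"""Mapping annotation sets and expression-derived gene sets onto zones.

Two percentage conventions are needed by the reporting tables and both are
supported explicitly:

``basis="zone"``
    percentage = 100 * count / zone size — "what fraction of zone k carries
    this annotation" (essential / disease / drug-target style tables).
``basis="set"``
    percentage = 100 * count / (members mapped into the network) — "how is
    this gene set distributed across zones" (consistent-expression style
    tables, whose rows sum to ~100%).

Gene-to-protein mapping is identity: gene expression is used as a proxy for
protein expression, with no ortholog or transcript resolution.  Members that
hit the centre are reported in a separate zone-0 row, never folded into
zone 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from pinzones._rounding import percent, round_half_away
from pinzones.metric_space import ZoneDecomposition
from pinzones.network_io import AnnotationSet, PresenceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZoneDistributionReport:
    """Per-zone membership counts for one annotation set.

    ``counts`` holds the exact intersection size per zone (including zone 0
    when the centre is annotated); ``zone_sizes`` the zone sizes of the
    decomposition; ``mapped_total`` the number of members landing in any
    zone; ``unmapped`` the number of members not present in the zoned part
    of the network.
    """

    name: str
    counts: Mapping[int, int]
    zone_sizes: Mapping[int, int]
    basis: str = "zone"
    unmapped: int = 0

    @property
    def mapped_total(self) -> int:
        return sum(self.counts.values())

    def percentage(self, zone: int) -> float:
        """Percentage for one zone under this report's basis, one decimal."""
        denom = self.zone_sizes.get(zone, 0) if self.basis == "zone" else self.mapped_total
        return percent(self.counts.get(zone, 0), denom)

    @property
    def percentages(self) -> dict[int, float]:
        return {k: self.percentage(k) for k in sorted(self.zone_sizes)}

    def to_frame(self) -> pd.DataFrame:
        zones = sorted(self.zone_sizes)
        return pd.DataFrame(
            {
                "zone": zones,
                "count": [self.counts.get(k, 0) for k in zones],
                "zone_size": [self.zone_sizes[k] for k in zones],
                "percent": [self.percentage(k) for k in zones],
            }
        ).set_index("zone")


@dataclass(frozen=True)
class ConsistentGeneSet:
    """Genes called present in at least ``threshold`` of a source's samples."""

    label: str
    threshold: float
    members: frozenset[str]

    def as_annotation(self) -> AnnotationSet:
        return AnnotationSet(name=self.label, members=self.members)


def zone_distribution(
    decomposition: ZoneDecomposition,
    annotation: AnnotationSet,
    basis: str = "zone",
) -> ZoneDistributionReport:
    """Count annotation members per zone and report percentages.

    Counts are exact set intersections with each zone (zone 0 = centres
    reported separately); members absent from the zoned network are logged
    and counted as unmapped.  An empty annotation yields a valid all-zero
    report with a warning.
    """
    if basis not in ("zone", "set"):
        raise ValueError(f"unknown percentage basis {basis!r}")
    if not annotation.members:
        logger.warning("annotation %r is empty", annotation.name)
    zone_sizes = decomposition.zone_sizes(include_centre=True)
    counts: dict[int, int] = {}
    unmapped = 0
    for member in annotation.members:
        zone = decomposition.zone_of.get(member)
        if zone is None:
            unmapped += 1
        else:
            counts[zone] = counts.get(zone, 0) + 1
    if unmapped:
        logger.info(
            "annotation %r: %d member(s) not in the zoned network", annotation.name, unmapped
        )
    return ZoneDistributionReport(
        name=annotation.name,
        counts=counts,
        zone_sizes=zone_sizes,
        basis=basis,
        unmapped=unmapped,
    )


def filter_consistent_genes(
    matrix: PresenceMatrix,
    threshold: float = 0.99,
    label: str = "consistent",
) -> ConsistentGeneSet:
    """Keep genes present in >= ``threshold`` of samples (boundary inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n_samples = len(matrix.samples)
    if n_samples == 0:
        raise ValueError("presence matrix has no samples")
    fractions = matrix.calls.sum(axis=1) / n_samples
    members = frozenset(fractions.index[fractions >= threshold])
    return ConsistentGeneSet(label=label, threshold=threshold, members=members)


def mean_percentage_row(
    rows: Iterable[Mapping[int, float]],
    zones: Sequence[int] | None = None,
) -> dict[int, float]:
    """Unweighted mean of per-set percentage rows, one decimal per zone.

    This is the arithmetic of a distribution table's "Average" row: each
    set's (already rounded) percentages contribute equally regardless of
    set size.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to average")
    if zones is None:
        zones = sorted({k for row in rows for k in row})
    return {
        k: round_half_away(sum(row.get(k, 0.0) for row in rows) / len(rows), 1) for k in zones
    }


def multi_set_distribution(
    decomposition: ZoneDecomposition,
    annotations: Sequence[AnnotationSet],
    basis: str = "set",
) -> tuple[list[ZoneDistributionReport], dict[int, float]]:
    """Per-set zone distributions plus the unweighted average percentage row."""
    if not annotations:
        raise ValueError("need at least one annotation set")
    reports = [zone_distribution(decomposition, aset, basis=basis) for aset in annotations]
    average = mean_percentage_row([r.percentages for r in reports])
    return reports, average


def distribution_matrix(
    reports: Sequence[ZoneDistributionReport],
    average: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Sets x zones percentage matrix, optionally with an Average row."""
    zones = sorted({k for r in reports for k in r.zone_sizes})
    data = {r.name: [r.percentage(k) for k in zones] for r in reports}
    frame = pd.DataFrame(data, index=zones).T
    frame.columns = [f"zone_{k}" for k in zones]
    frame.index.name = "set"
    if average is not None:
        frame.loc["Average"] = [average.get(k, 0.0) for k in zones]
    return frame
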