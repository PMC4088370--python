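import numpy as np
import pytest
from scipy import stats

from pinzones import reference
from pinzones.metric_space import ZoneDecomposition
from pinzones.network_io import AnnotationSet
from pinzones.zone_annotation import ZoneDistributionReport, zone_distribution
from pinzones.zone_stats import (
    fisher_exact_p,
    hypergeometric_enrichment,
    pairwise_zone_tests,
    pathway_zone_proportions,
    two_proportion_z,
)

from _oracles import hypergeometric_upper_tail


class TestTwoProportionZ:
    def test_identical_proportions_give_zero(self):
        res = two_proportion_z(50, 100, 50, 100)
        assert res.z == 0.0 and res.p_value == 1.0 and not res.significant

    def test_zone1_vs_zone2_essential_counts(self):
        """Pooled z on the reported zone-1/zone-2 essential counts is ~9.37."""
        res = two_proportion_z(161, 374, 1002, 4610)
        assert res.z == pytest.approx(9.3721, abs=1e-3)
        assert res.p_value < 0.01 and res.significant
        # significance agrees with Fisher's exact test on the same table
        assert fisher_exact_p(161, 374, 1002, 4610) < 0.01

    def test_degenerate_all_zero_counts(self):
        res = two_proportion_z(0, 10, 0, 10)
        assert res.z == 0.0 and not res.significant

    def test_degenerate_all_one_counts(self):
        res = two_proportion_z(10, 10, 7, 7)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_antisymmetry(self):
        """Swapping the samples negates z and preserves the p-value."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            n1, n2 = rng.integers(1, 60, size=2)
            c1, c2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            fwd = two_proportion_z(int(c1), int(n1), int(c2), int(n2))
            rev = two_proportion_z(int(c2), int(n2), int(c1), int(n1))
            assert fwd.z == pytest.approx(-rev.z)
            assert fwd.p_value == pytest.approx(rev.p_value)

    def test_z_sign_matches_proportion_difference(self):
        assert two_proportion_z(8, 10, 2, 10).z > 0
        assert two_proportion_z(2, 10, 8, 10).z < 0

    def test_one_sided_mode(self):
        two_sided = two_proportion_z(30, 100, 15, 100)
        larger = two_proportion_z(30, 100, 15, 100, alternative="larger")
        assert larger.p_value == pytest.approx(two_sided.p_value / 2)

    def test_matches_statsmodels_pooled_z(self):
        """Cross-check the statistic against an independent implementation."""
        from statsmodels.stats.proportion import proportions_ztest

        for c1, n1, c2, n2 in [(161, 374, 1002, 4610), (5, 20, 9, 30), (1, 7, 6, 9)]:
            expected_z, expected_p = proportions_ztest([c1, c2], [n1, n2])
            res = two_proportion_z(c1, n1, c2, n2)
            assert res.z == pytest.approx(float(expected_z))
            assert res.p_value == pytest.approx(float(expected_p))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_proportion_z(1, 0, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_z(11, 10, 1, 10)


class TestFisherAgreement:
    def test_small_sample_sweep_agreement(self):
        """z-test vs Fisher significance at alpha=0.01, all tables n1,n2 <= 12.

        The pooled z-test is anticonservative in a small, stable set of
        borderline tables; outside it the two tests agree.
        """
        alpha = 0.01
        disagreements = []
        for n1 in range(1, 13):
            for n2 in range(1, 13):
                for c1 in range(n1 + 1):
                    for c2 in range(n2 + 1):
                        z_sig = two_proportion_z(c1, n1, c2, n2).p_value < alpha
                        f_sig = fisher_exact_p(c1, n1, c2, n2) < alpha
                        if z_sig != f_sig:
                            disagreements.append((n1, n2, c1, c2))
        # frozen from this exhaustive enumeration: all disagreements are
        # z-significant/Fisher-not (anticonservative direction)
        assert len(disagreements) == 512
        assert all(
            two_proportion_z(c1, n1, c2, n2).p_value < alpha
            for n1, n2, c1, c2 in disagreements
        )


class TestPairwiseZoneTests:
    def make_report(self, counts, sizes):
        return ZoneDistributionReport(name="t", counts=counts, zone_sizes=sizes)

    def test_identical_proportions_not_significant(self):
        report = self.make_report({1: 10, 2: 20}, {1: 100, 2: 200})
        results = pairwise_zone_tests(report)
        assert len(results) == 1 and not results[0].significant

    def test_reported_essential_adjacent_pairs(self):
        """Adjacent-zone tests on the reported essential counts.

        Zones 1-2 and 2-3 differ sharply; the proportions of zones 3-5
        (~11%, ~9.5%, ~9.6%) do not separate at alpha=0.01 — confirmed
        against Fisher's exact test.
        """
        report = self.make_report(
            dict(reference.HFPIN_ESSENTIAL),
            {k: reference.HFPIN_ZONE_SIZES[k] for k in reference.HFPIN_ESSENTIAL},
        )
        results = pairwise_zone_tests(report, pairs="adjacent")
        by_pair = {(r.label1, r.label2): r for r in results}
        assert by_pair[("zone 1", "zone 2")].significant
        assert by_pair[("zone 2", "zone 3")].significant
        assert not by_pair[("zone 3", "zone 4")].significant
        assert not by_pair[("zone 4", "zone 5")].significant
        for r in results:
            fisher_sig = fisher_exact_p(r.count1, r.n1, r.count2, r.n2) < 0.01
            assert fisher_sig == r.significant

    def test_all_pairs_count(self):
        report = self.make_report({1: 5, 2: 5, 3: 5}, {1: 50, 2: 50, 3: 50})
        assert len(pairwise_zone_tests(report, pairs="all")) == 3
        assert len(pairwise_zone_tests(report, pairs="adjacent")) == 2

    def test_zero_size_zone_skipped(self, caplog):
        report = self.make_report({1: 5, 3: 5}, {1: 50, 2: 0, 3: 50})
        with caplog.at_level("WARNING"):
            results = pairwise_zone_tests(report)
        assert len(results) == 1 and "size 0" in caplog.text

    def test_single_zone_raises(self):
        with pytest.raises(ValueError):
            pairwise_zone_tests(self.make_report({1: 5}, {1: 50}))

    def test_bonferroni_scales_p(self):
        report = self.make_report({1: 30, 2: 10, 3: 5}, {1: 100, 2: 100, 3: 100})
        raw = pairwise_zone_tests(report)
        corrected = pairwise_zone_tests(report, bonferroni=True)
        for r, c in zip(raw, corrected):
            assert c.p_value == pytest.approx(min(1.0, r.p_value * 3))


class TestHypergeometricEnrichment:
    def test_exact_example_value(self):
        """Universe 20, pathway 5, zone 10, overlap 5: p = 21/1292 ~ 0.0163."""
        universe = [f"g{i}" for i in range(20)]
        pathway = AnnotationSet("p", frozenset(universe[:5]))
        zone = set(universe[:5]) | set(universe[10:15])
        (res,) = hypergeometric_enrichment(zone, [pathway], universe)
        assert res.overlap == 5
        assert res.p_raw == pytest.approx(21 / 1292)

    def test_pathway_equals_universe_is_saturated(self):
        universe = [f"g{i}" for i in range(8)]
        pathway = AnnotationSet("all", frozenset(universe))
        (res,) = hypergeometric_enrichment(universe[:4], [pathway], universe)
        assert res.p_raw == pytest.approx(1.0)

    def test_zero_overlap_retained_with_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        pathway = AnnotationSet("p", frozenset(universe[5:]))
        (res,) = hypergeometric_enrichment(universe[:3], [pathway], universe)
        assert res.overlap == 0 and res.p_raw == 1.0

    def test_bonferroni_monotone_and_capped(self):
        universe = [f"g{i}" for i in range(20)]
        pathways = [AnnotationSet(f"p{j}", frozenset(universe[j : j + 5])) for j in range(6)]
        results = hypergeometric_enrichment(universe[:5], pathways, universe)
        for res in results:
            assert res.p_corrected == pytest.approx(min(1.0, res.p_raw * 6))
        assert results == sorted(results, key=lambda r: (r.p_corrected, r.p_raw, r.pathway))

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), [AnnotationSet("p", frozenset())], set())

    @pytest.mark.parametrize("population,successes,draws", [(8, 3, 4), (10, 5, 5), (12, 4, 6)])
    def test_matches_enumeration_oracle(self, population, successes, draws):
        """Raw p equals brute-force enumeration of all draws (tiny universes)."""
        universe = [f"g{i}" for i in range(population)]
        pathway = AnnotationSet("p", frozenset(universe[:successes]))
        for overlap in range(1, min(successes, draws) + 1):
            zone = set(universe[:overlap]) | set(universe[successes:][: draws - overlap])
            assert len(zone) == draws
            (res,) = hypergeometric_enrichment(zone, [pathway], universe)
            expected = hypergeometric_upper_tail(population, successes, draws, res.overlap)
            assert res.p_raw == pytest.approx(float(expected), rel=1e-9)


class TestPathwayZoneProportions:
    def make_decomposition(self):
        zone_of = {"C": 0}
        zone_of.update({f"a{i}": 1 for i in range(4)})
        zone_of.update({f"b{i}": 2 for i in range(4)})
        return ZoneDecomposition(
            centres=frozenset({"C"}), zone_of=zone_of, radius=2, diameter=3
        )

    def test_pathway_covering_one_zone(self):
        dec = self.make_decomposition()
        pathway = AnnotationSet("p", frozenset(f"a{i}" for i in range(4)))
        assert pathway_zone_proportions(dec, pathway) == {1: 1.0, 2: 0.0}

    def test_empty_pathway_all_zero(self):
        dec = self.make_decomposition()
        assert pathway_zone_proportions(dec, AnnotationSet("p", frozenset())) == {
            1: 0.0,
            2: 0.0,
        }

    def test_matches_zone_distribution_arithmetic(self):
        dec = self.make_decomposition()
        pathway = AnnotationSet("p", frozenset({"a0", "a1", "b0"}))
        proportions = pathway_zone_proportions(dec, pathway)
        report = zone_distribution(dec, pathway)
        for k, frac in proportions.items():
            assert frac == report.counts.get(k, 0) / report.zone_sizes[k]
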