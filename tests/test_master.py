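"""Monte Carlo enrichment core: weighted scores, null sampling, empirical p."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirreg.catalog import Catalog, GeneRecord, SiteType
from mirreg.expression import DERecord, FeatureKind, Thresholds
from mirreg.master import (
    NullDistribution,
    empirical_pvalue,
    identify_master_regulators,
    null_distribution,
    sample_background,
    targetscan_universe,
    utr_length_normalise,
    weighted_utr_score,
)

from conftest import make_site


class TestWeightedUtrScore:
    def test_empty(self):
        assert weighted_utr_score([]) == 0.0

    @pytest.mark.parametrize("types, offsets, expected", [
        ([SiteType.EIGHT_MER], [100], 1.0),
        ([SiteType.SEVEN_MER_M8], [100], 0.75),
        ([SiteType.SEVEN_MER_A1], [100], 0.5),
        ([SiteType.SIX_MER], [100], 0.25),
        # cooperative spacing: gap 20 in [13, 46] earns the pair bonus
        ([SiteType.EIGHT_MER, SiteType.EIGHT_MER], [100, 120], 2.2),
        # gap 12 just below, gap 47 just above: no bonus
        ([SiteType.EIGHT_MER, SiteType.EIGHT_MER], [100, 112], 2.0),
        ([SiteType.EIGHT_MER, SiteType.EIGHT_MER], [100, 147], 2.0),
        # chain of three cooperative sites: two consecutive bonuses
        ([SiteType.SIX_MER] * 3, [0, 20, 40], 0.75 + 0.4),
    ])
    def test_weights_and_spacing(self, types, offsets, expected):
        sites = [make_site(offset=o, site_type=t) for t, o in zip(types, offsets)]
        assert weighted_utr_score(sites) == pytest.approx(expected)

    def test_offset_order_irrelevant(self):
        sites = [make_site(offset=o) for o in (120, 100)]
        assert weighted_utr_score(sites) == pytest.approx(2.2)

    def test_mixed_pairs_rejected(self):
        sites = [make_site(gene="G1"), make_site(gene="G2")]
        with pytest.raises(ValueError):
            weighted_utr_score(sites)


@pytest.fixture
def universe5():
    return [GeneRecord(f"G{i}", 1000 + 100 * i) for i in range(5)]


class TestSampleBackground:
    def test_full_universe_and_empty(self, universe5):
        assert sample_background(universe5, 5, 0) == {g.gene_id for g in universe5}
        assert sample_background(universe5, 0, 0) == set()

    def test_reproducible(self, universe5):
        assert sample_background(universe5, 3, 42) == sample_background(universe5, 3, 42)

    def test_oversampling_rejected(self, universe5):
        with pytest.raises(ValueError):
            sample_background(universe5, 6, 0)


class TestNullDistribution:
    def test_no_targets_all_zero(self, universe5):
        null = null_distribution("miR-x", {}, universe5, 2, 200, 0)
        assert np.all(null.values == 0)

    def test_saturation(self, universe5):
        targets = {g.gene_id: 1.0 for g in universe5}
        null = null_distribution("miR-x", targets, universe5, 3, 200, 0)
        assert np.all(null.values == 3)

    def test_hypergeometric_mean(self, universe5):
        # 2 targeted genes of 5, samples of 2: E[count] = 2*2/5 = 0.8
        targets = {"G0": 1.0, "G1": 1.0}
        b = 20000
        null = null_distribution("miR-x", targets, universe5, 2, b, 1)
        se = math.sqrt(null.values.var() / b)
        assert null.values.mean() == pytest.approx(0.8, abs=3 * se)

    def test_background_mean_utr_matches_population(self, universe5):
        null = null_distribution("miR-x", {}, universe5, 5, 50, 0)
        assert null.background_mean_utr == pytest.approx(
            np.mean([g.utr_length for g in universe5]))

    def test_reproducible_under_seed(self, universe5):
        a = null_distribution("miR-x", {"G0": 1.0}, universe5, 2, 100, 7)
        b = null_distribution("miR-x", {"G0": 1.0}, universe5, 2, 100, 7)
        assert np.array_equal(a.values, b.values)


class TestNormalisationAndPvalue:
    def test_equal_means_unchanged(self):
        assert utr_length_normalise(5.0, 1200.0, 1200.0) == 5.0

    def test_length_correction(self):
        assert utr_length_normalise(10.0, 1500.0, 1000.0) == pytest.approx(6.667, abs=1e-3)

    def test_zero_observed(self):
        assert utr_length_normalise(0.0, 800.0, 1000.0) == 0.0

    def test_non_positive_means_rejected(self):
        with pytest.raises(ValueError):
            utr_length_normalise(1.0, 0.0, 1000.0)

    def test_empirical_pvalue_counts_ties_as_exceedance(self):
        null = NullDistribution("m", "target_count", np.array([0, 1, 2, 3, 4.0]), 1.0)
        assert empirical_pvalue(3.0, null) == pytest.approx(0.5)  # (1+2)/6

    def test_empirical_pvalue_bounds(self):
        null = NullDistribution("m", "target_count", np.arange(5.0), 1.0)
        assert empirical_pvalue(0.0, null) == 1.0
        assert empirical_pvalue(100.0, null) == pytest.approx(1 / 6)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            NullDistribution("m", "target_count", np.array([]), 1.0)


def exact_enumeration_pvalue(contrib, utr, group_idx, normalise=True):
    """Independent oracle: exact exceedance over all size-n subsets."""
    from itertools import combinations

    n = len(group_idx)
    observed = sum(contrib[i] for i in group_idx)
    subsets = list(combinations(range(len(contrib)), n))
    null_vals = [sum(contrib[i] for i in s) for s in subsets]
    bg_mean = float(np.mean([utr[i] for s in subsets for i in s]))
    group_mean = float(np.mean([utr[i] for i in group_idx]))
    obs = observed * bg_mean / group_mean if normalise else observed
    return sum(v >= obs for v in null_vals) / len(null_vals), obs


class TestExactOracle:
    def test_monte_carlo_agrees_with_enumeration_on_tiny_universe(self):
        """6-gene universe, 2-gene group: MC empirical p within 3 SE of exact."""
        rng = np.random.default_rng(5)
        b = 5000
        for _ in range(3):
            utr = rng.integers(500, 3000, size=6)
            targeted = rng.random(6) < 0.5
            contrib = targeted.astype(float)
            universe = [GeneRecord(f"G{i}", int(utr[i])) for i in range(6)]
            targets = {f"G{i}": 1.0 for i in range(6) if targeted[i]}
            group = [0, 1]
            null = null_distribution("m", targets, universe, 2, b, rng)
            observed = sum(contrib[i] for i in group)
            obs_norm = utr_length_normalise(
                observed, float(np.mean(utr[group])), null.background_mean_utr
            ) if observed else 0.0
            p_mc = empirical_pvalue(obs_norm, null)
            # oracle at the same normalised observed value
            from itertools import combinations
            null_exact = [sum(contrib[i] for i in s)
                          for s in combinations(range(6), 2)]
            p_exact = sum(v >= obs_norm for v in null_exact) / len(null_exact)
            se = math.sqrt(max(p_exact * (1 - p_exact), 1e-12) / b)
            assert abs(p_mc - p_exact) <= 3 * se + 2 / (b + 1)


def _catalog_with_targets(n_genes=12, targeted=(0, 1, 2, 3)):
    from mirreg.catalog import ConservationClass, MiRNARecord

    genes = tuple(GeneRecord(f"G{i}", 1000) for i in range(n_genes))
    mirna = MiRNARecord("miR-t", "hsa-mir-t", ConservationClass.BROADLY_CONSERVED)
    sites = tuple(make_site("miR-t", f"G{i}", 50, microt=0.8, mirsvr=-0.5)
                  for i in range(n_genes))  # TargetScan site everywhere
    # only `targeted` genes get consensus support; others TargetScan-only
    sites = tuple(
        make_site("miR-t", f"G{i}", 50,
                  microt=0.8 if i in targeted else None,
                  mirsvr=-0.5 if i in targeted else None)
        for i in range(n_genes)
    )
    return Catalog(genes, (mirna,), sites)


class TestIdentifyMasterRegulators:
    def make_de(self, gene_ids, mirna_ids, line="A"):
        genes = [DERecord(g, FeatureKind.GENE, line, 1.5, 0.001, 0.01)
                 for g in gene_ids]
        mirnas = [DERecord(m, FeatureKind.MIRNA, line, -1.5, 0.001)
                  for m in mirna_ids]
        return mirnas, genes

    def test_no_consensus_targets_gives_p_one(self):
        catalog = _catalog_with_targets(targeted=())
        mirnas, genes = self.make_de([f"G{i}" for i in range(4)], ["miR-t"])
        thr = Thresholds(mc_iterations=50)
        results = identify_master_regulators(mirnas, genes, catalog, thr, 0)
        assert len(results) == 1
        assert results[0].empirical_p == 1.0
        assert not results[0].is_master

    def test_deterministic_and_order_invariant(self):
        catalog = _catalog_with_targets()
        mirnas, genes = self.make_de([f"G{i}" for i in range(6)], ["miR-t"])
        thr = Thresholds(mc_iterations=100)
        a = identify_master_regulators(mirnas, genes, catalog, thr, 3)
        b = identify_master_regulators(list(reversed(mirnas)),
                                       list(reversed(genes)), catalog, thr, 3)
        assert a == b

    def test_direction_assignment(self):
        catalog = _catalog_with_targets()
        genes = [DERecord("G0", FeatureKind.GENE, "A", 1.5, 0.001, 0.01),
                 DERecord("G1", FeatureKind.GENE, "A", -1.5, 0.001, 0.01)]
        up_mirna = [DERecord("miR-t", FeatureKind.MIRNA, "A", 1.2, 0.001)]
        down_mirna = [DERecord("miR-t", FeatureKind.MIRNA, "A", -1.2, 0.001)]
        thr = Thresholds(mc_iterations=50)
        up = identify_master_regulators(up_mirna, genes, catalog, thr, 0)
        down = identify_master_regulators(down_mirna, genes, catalog, thr, 0)
        assert up[0].direction == "mirna_up_genes_down"
        assert down[0].direction == "mirna_down_genes_up"

    def test_observed_count_is_integer_bounded_by_group(self):
        catalog = _catalog_with_targets()
        mirnas, genes = self.make_de([f"G{i}" for i in range(6)], ["miR-t"])
        thr = Thresholds(mc_iterations=50)
        [res] = identify_master_regulators(mirnas, genes, catalog, thr, 0)
        assert res.observed_raw == int(res.observed_raw)
        assert 0 <= res.observed_raw <= 6

    def test_empty_gene_group_skipped(self, caplog):
        catalog = _catalog_with_targets()
        mirnas, _ = self.make_de([], ["miR-t"])
        thr = Thresholds(mc_iterations=50)
        results = identify_master_regulators(mirnas, [], catalog, thr, 0)
        assert results == []

    def test_weighted_statistic_runs(self):
        catalog = _catalog_with_targets()
        mirnas, genes = self.make_de([f"G{i}" for i in range(6)], ["miR-t"])
        thr = Thresholds(mc_iterations=50)
        [res] = identify_master_regulators(mirnas, genes, catalog, thr, 0,
                                           statistic="weighted_score")
        assert res.statistic_kind == "weighted_score"
        assert res.observed_raw >= 0
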