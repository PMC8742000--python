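"""Statistical core: chi-squared testing, correction, fold change, window detection."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency

import medseq as m
from medseq import dmr as dmrlib
from medseq.dmr import (DmrConfig, GroupContrast, adjust_pvalues,
                        call_group_unique_dmrs, chi_squared_2x2,
                        detect_dmrs_sliding_window, fold_change,
                        window_members, DMR)
from medseq.matrix import SiteCountMatrix

from conftest import recovered_planted


class TestChiSquared2x2:
    def test_identical_proportions_give_null(self):
        assert chi_squared_2x2(10, 1000, 10, 1000) == (0.0, 1.0)

    def test_hand_computed_extreme_table(self):
        # [[10, 0], [0, 10]]: n(ad-bc)^2 / product of marginals = 20*(100)^2/10^4 = 20
        stat, p = chi_squared_2x2(10, 10, 0, 10)
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(float(chi2_dist.sf(20.0, 1)))

    def test_zero_marginal_returns_null(self):
        assert chi_squared_2x2(0, 100, 0, 50) == (0.0, 1.0)

    @pytest.mark.parametrize("args", [(0, 0, 0, 0), (-1, 10, 0, 10), (11, 10, 0, 10)])
    def test_invalid_tables_rejected(self, args):
        with pytest.raises(ValueError):
            chi_squared_2x2(*args)

    def test_matches_pearson_oracle_on_random_tables(self):
        """1000 random 2x2 tables against scipy's uncorrected Pearson test."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 1000:
            total_a, total_b = rng.integers(5, 5000, size=2)
            a = int(rng.integers(0, total_a + 1))
            b = int(rng.integers(0, total_b + 1))
            table = np.array([[a, total_a - a], [b, total_b - b]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            stat, p = chi_squared_2x2(a, int(total_a), b, int(total_b))
            ref = chi2_contingency(table, correction=False)
            assert abs(stat - ref.statistic) < 1e-9
            assert abs(p - ref.pvalue) < 1e-9
            checked += 1


class TestAdjustPvalues:
    def test_bonferroni_definition(self):
        assert adjust_pvalues([0.01, 0.4], "bonferroni").tolist() == [0.02, 0.8]

    def test_bh_step_up_hand_computed(self):
        # ranks 1..4: min over j>=i of p_j * n/j = [0.04, 0.04, 0.04, 0.04]
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_certain_pvalue_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([1.0], method).tolist() == [1.0]

    def test_empty_vector_passthrough(self):
        assert adjust_pvalues([], "bh").size == 0

    def test_bh_matches_independent_step_up_oracle(self):
        def bh_oracle(p):
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            assert np.allclose(adjust_pvalues(p, "bh"), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bonferroni")


class TestFoldChange:
    def test_simple_ratio(self):
        assert fold_change(20, 10**6, 10, 10**6, pseudocount=0) == pytest.approx(2.0)

    def test_symmetric_null_with_pseudocount(self):
        assert fold_change(0, 10**6, 0, 10**6, pseudocount=0.5) == 1.0

    def test_library_size_invariance(self):
        assert fold_change(40, 2 * 10**6, 10, 10**6, pseudocount=0) == pytest.approx(2.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1, 0, 1, 100)


def _dense_matrix(positions, count_a, count_b, n_per_group=2, background=500):
    """Matrix with two groups whose pooled counts at the given sites are fixed,
    embedded in a larger null background so totals are realistic."""
    n = len(positions)
    rng = np.random.default_rng(99)
    counts = np.zeros((n, 2 * n_per_group), dtype=np.int64)
    for j in range(n_per_group):
        counts[:, j] = count_a // n_per_group
        counts[:, n_per_group + j] = count_b // n_per_group
    samples = [f"A{j}" for j in range(n_per_group)] + [f"B{j}" for j in range(n_per_group)]
    totals = {s: int(counts[:, i].sum()) + background * 1000 for i, s in enumerate(samples)}
    groups = {s: s[0] for s in samples}
    cat = m.SiteCatalog(pd.DataFrame({"chrom": "chr1", "pos": positions, "strand": "+"}))
    mat = SiteCountMatrix(np.arange(n), samples, counts, totals, groups)
    return cat, mat


class TestSlidingWindow:
    def test_neighbor_budget_caps_examined_sites(self):
        positions = np.arange(0, 1000, 5)      # 200 sites, 5 bp apart
        left, right = window_members(positions, 100, max_neighbors=50, max_distance_bp=1000)
        assert len(left) == 50 and len(right) == 50

    def test_distance_limit_caps_window(self):
        positions = np.arange(0, 20000, 100)   # 100 bp apart: distance binds first
        left, right = window_members(positions, 100, max_neighbors=50, max_distance_bp=1000)
        assert len(left) == 10 and len(right) == 10
        assert positions[left].min() >= positions[100] - 1000

    def test_planted_dmrs_recovered_with_direction(self, toy_catalog, counts_ab, profile_ab):
        by_contrast = {
            c.name: detect_dmrs_sliding_window(counts_ab, toy_catalog, c)
            for c in m.one_vs_rest_contrasts(counts_ab.groups)
        }
        hits = recovered_planted(profile_ab.planted_dmrs, by_contrast)
        assert hits.mean() >= 0.9

    def test_emitted_dmrs_satisfy_all_thresholds(self, toy_catalog, counts_ab, contrast_a):
        config = DmrConfig()
        for d in detect_dmrs_sliding_window(counts_ab, toy_catalog, contrast_a, config):
            assert d.n_significant_sites >= config.min_sites
            assert d.span >= config.min_span_bp
            assert (d.fold_change >= config.fc_threshold
                    or d.fold_change <= 1 / config.fc_threshold)

    def test_eight_site_cluster_below_minimum_not_emitted(self, toy_fixture):
        """A differential run of only 8 sites must never produce a DMR."""
        baseline = np.full(toy_fixture.n_sites, 0.1)
        elevated = baseline.copy()
        elevated[100:108] = 0.4
        profile = m.MethylationProfile(
            groups={"A": elevated, "B": baseline}, planted_dmrs=[], baseline=0.1
        )
        mat = m.simulate_count_matrix(profile, 6, 100_000, seed=17)
        contrast = GroupContrast("A_vs_rest", mat.group_samples("A"), mat.group_samples("B"))
        dmrs = detect_dmrs_sliding_window(mat, toy_fixture.to_catalog(), contrast)
        cat = toy_fixture.to_catalog().frame()
        lo, hi = cat["pos"].iloc[100], cat["pos"].iloc[107]
        assert not any(d.start <= hi and lo <= d.end for d in dmrs)

    def test_narrow_cluster_below_span_not_emitted(self):
        # 12 strongly differential sites spanning 59 bp < 100 bp minimum
        positions = list(range(1000, 1060, 5))
        cat, mat = _dense_matrix(positions, count_a=20000, count_b=1000)
        contrast = GroupContrast("A_vs_rest", ["A0", "A1"], ["B0", "B1"])
        assert detect_dmrs_sliding_window(mat, cat, contrast) == []

    def test_wide_cluster_emitted(self):
        positions = list(range(1000, 1600, 50))   # 12 sites over 554 bp
        cat, mat = _dense_matrix(positions, count_a=20000, count_b=1000)
        contrast = GroupContrast("A_vs_rest", ["A0", "A1"], ["B0", "B1"])
        dmrs = detect_dmrs_sliding_window(mat, cat, contrast)
        assert len(dmrs) == 1
        assert dmrs[0].direction == "hyper" and dmrs[0].span >= 100

    def test_fc_threshold_monotonicity(self, toy_catalog, counts_ab, contrast_a):
        n2 = len(detect_dmrs_sliding_window(counts_ab, toy_catalog, contrast_a,
                                            DmrConfig(fc_threshold=2.0)))
        n5 = len(detect_dmrs_sliding_window(counts_ab, toy_catalog, contrast_a,
                                            DmrConfig(fc_threshold=5.0)))
        assert n5 <= n2

    def test_pooling_invariance_under_sample_relabeling(self, toy_catalog, counts_ab):
        a = counts_ab.group_samples("A")
        b = counts_ab.group_samples("B")
        d1 = detect_dmrs_sliding_window(counts_ab, toy_catalog,
                                        GroupContrast("c", a, b))
        d2 = detect_dmrs_sliding_window(counts_ab, toy_catalog,
                                        GroupContrast("c", a[::-1], b[::-1]))
        assert [(x.start, x.end, x.fold_change, x.p_value) for x in d1] == \
               [(x.start, x.end, x.fold_change, x.p_value) for x in d2]

    def test_null_profile_produces_no_false_positives_on_average(self, toy_fixture):
        """Identical group methylomes: Bonferroni keeps mean FP DMRs/run < 1."""
        baseline = np.full(toy_fixture.n_sites, 0.1)
        profile = m.MethylationProfile(
            groups={"A": baseline, "B": baseline.copy()}, planted_dmrs=[], baseline=0.1
        )
        catalog = toy_fixture.to_catalog()
        fp = 0
        n_seeds = 20
        for seed in range(n_seeds):
            mat = m.simulate_count_matrix(profile, 6, 50_000, seed=1000 + seed)
            contrast = GroupContrast("A_vs_rest", mat.group_samples("A"),
                                     mat.group_samples("B"))
            fp += len(detect_dmrs_sliding_window(mat, catalog, contrast))
        assert fp / n_seeds < 1


class TestGroupUniqueDmrs:
    def _dmr(self, start, end, contrast, chrom="chr1"):
        return DMR(chrom=chrom, start=start, end=end, site_ids=[],
                   n_significant_sites=10, count_a=0, count_b=0, fold_change=3.0,
                   direction="hyper", p_value=1e-9, adjusted_p=1e-6, contrast=contrast)

    def test_non_overlapping_dmr_is_unique(self):
        by = {"A_vs_rest": [self._dmr(100, 400, "A_vs_rest")],
              "B_vs_rest": [self._dmr(5000, 5400, "B_vs_rest")]}
        unique = call_group_unique_dmrs(by)
        assert len(unique["A_vs_rest"]) == 1 and len(unique["B_vs_rest"]) == 1

    def test_single_bp_overlap_excludes_both(self):
        by = {"A_vs_rest": [self._dmr(100, 401, "A_vs_rest")],
              "B_vs_rest": [self._dmr(400, 700, "B_vs_rest")]}
        unique = call_group_unique_dmrs(by)
        assert unique["A_vs_rest"] == [] and unique["B_vs_rest"] == []

    def test_requires_at_least_two_contrasts(self):
        with pytest.raises(ValueError):
            call_group_unique_dmrs({"only": []})

    def test_synthetic_group_exclusive_dmrs_recovered(self):
        """Three groups, moderate effect: unique sets carry the planted labels."""
        fx = m.generate_toy_genome(1, 100_000, 100, seed=23)
        prof = m.plant_methylation(fx, ["A", "B", "C"], 6, 12, 2.5, 0.1, seed=8)
        mat = m.simulate_count_matrix(prof, 6, 100_000, seed=31)
        catalog = fx.to_catalog()
        by = {c.name: detect_dmrs_sliding_window(mat, catalog, c)
              for c in m.one_vs_rest_contrasts(mat.groups)}
        unique = call_group_unique_dmrs(by)
        for d in prof.planted_dmrs:
            own = [u for u in unique[f"{d.group}_vs_rest"]
                   if u.start < d.end and d.start < u.end]
            assert own, f"planted {d.group} DMR at {d.start} not recovered as unique"
            foreign = [u for name, lst in unique.items() for u in lst
                       if name != f"{d.group}_vs_rest" and u.start < d.end and d.start < u.end]
            assert not foreign


class TestRegionLevelTesting:
    def test_planted_region_significant_with_direction(self, toy_fixture, toy_catalog,
                                                       profile_ab, counts_ab, contrast_a):
        planted = next(d for d in profile_ab.planted_dmrs if d.group == "A")
        genes = pd.DataFrame(
            [("chr1", planted.start - 200, planted.end + 200, "g1", "+")],
            columns=["chrom", "start", "end", "gene_id", "strand"],
        )
        regions = m.build_regions(genes, tss_flank=200)
        site_map = m.assign_sites(toy_catalog, regions)
        res = dmrlib.test_regions(counts_ab, site_map, regions, contrast_a)
        body = res[res["kind"] == "gene_body"].iloc[0]   # covers the planted interval
        assert body["n_sites"] >= 12
        assert bool(body["significant"])
        assert body["direction"] == planted.direction

    def test_region_without_sites_reported_na(self, toy_catalog, counts_ab, contrast_a):
        regions = m.RegionSet([m.catalog.Region(0, "chrNope", 0, 500, "TSS", "g", "+")])
        site_map = m.assign_sites(toy_catalog, regions)
        res = dmrlib.test_regions(counts_ab, site_map, regions, contrast_a)
        assert res["p"].isna().all() and (~res["significant"]).all()

    def test_overlapping_sample_sets_rejected(self, counts_ab):
        with pytest.raises(ValueError, match="share samples"):
            GroupContrast("bad", counts_ab.samples[:3], counts_ab.samples[2:5])

    def test_unknown_sample_rejected(self, toy_catalog, counts_ab):
        contrast = GroupContrast("c", ["ghost"], counts_ab.samples[6:])
        with pytest.raises(ValueError, match="ghost"):
            dmrlib.test_sites(counts_ab, contrast)
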