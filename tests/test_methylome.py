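"""Methylome statistics: caller calibration, pooling identities, DMV logic."""

import numpy as np
import pytest

from gymnome import methylome as me
from gymnome import synthetic_data as sd
from gymnome.errors import ValidationError
from gymnome.io_formats import CytosineRecord, GeneModel, Interval, ExpressionRecord


def C(pos, m, t, ctx="CG", chrom="chr1", strand="+"):
    return CytosineRecord(chrom, pos, strand, ctx, m, t)


class TestConversionRate:
    def test_all_converted(self):
        assert me.estimate_conversion_rate([C(1, 0, 10), C(2, 0, 5)]).rate == 1.0

    def test_arithmetic(self):
        est = me.estimate_conversion_rate([C(1, 3, 600), C(2, 2, 400)])
        assert est.rate == 0.995

    def test_zero_coverage_errors(self):
        with pytest.raises(ValidationError):
            me.estimate_conversion_rate([C(1, 0, 0)])


class TestCallMethylatedSites:
    conv = me.ConversionEstimate(990, 1000)  # rate 0.99 -> null p0 = 0.01

    def test_zero_methylated_never_called(self):
        (call,) = me.call_methylated_sites([C(1, 0, 10)], self.conv)
        assert call.p_value == pytest.approx(1.0)
        assert not call.is_methylated

    def test_fully_methylated_closed_form(self):
        (call,) = me.call_methylated_sites([C(1, 5, 5)], self.conv)
        assert call.p_value == pytest.approx(0.01**5, rel=1e-9)
        assert call.is_methylated

    def test_one_of_ten_closed_form(self):
        (call,) = me.call_methylated_sites([C(1, 1, 10)], self.conv)
        assert call.p_value == pytest.approx(1 - 0.99**10, rel=1e-9)

    def test_perfect_conversion_null(self):
        conv = me.ConversionEstimate(1000, 1000)
        calls = me.call_methylated_sites([C(1, 1, 10), C(2, 0, 10)], conv)
        assert calls[0].p_value == 0.0 and calls[1].p_value == 1.0

    def test_low_coverage_sites_excluded(self):
        calls = me.call_methylated_sites([C(1, 2, 3), C(2, 5, 5)], self.conv,
                                         min_coverage=4)
        assert len(calls) == 1 and calls[0].site.pos == 2

    def test_invalid_alpha_errors(self):
        with pytest.raises(ValidationError):
            me.call_methylated_sites([C(1, 1, 10)], self.conv, alpha=1.5)

    def test_type_one_error_controlled_on_null_simulation(self):
        p = sd.MethylomeSimParams(
            n_sites_per_context={"CG": 20_000, "CHG": 0, "CHH": 0},
            true_levels={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            non_conversion=0.005, mean_depth=20, seed=31,
        )
        recs, lam, _ = sd.simulate_methylome(p)
        conv = me.estimate_conversion_rate(lam)
        calls = me.call_methylated_sites(recs, conv)
        alpha = 0.05
        raw_rate = np.mean([c.p_value < alpha for c in calls])
        se = np.sqrt(alpha * (1 - alpha) / len(calls))
        assert raw_rate <= alpha + 3 * se
        assert np.mean([c.is_methylated for c in calls]) <= 0.001

    def test_power_on_methylated_sites(self):
        p = sd.MethylomeSimParams(
            n_sites_per_context={"CG": 10_000, "CHG": 0, "CHH": 0},
            true_levels={"CG": 0.8, "CHG": 0.0, "CHH": 0.0},
            non_conversion=0.005, mean_depth=20, seed=32,
        )
        recs, lam, _ = sd.simulate_methylome(p)
        conv = me.estimate_conversion_rate(lam)
        calls = me.call_methylated_sites(
            [r for r in recs if r.count_total >= 10], conv, min_coverage=10
        )
        assert np.mean([c.is_methylated for c in calls]) > 0.99


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg: sort, scale, cumulative min, clip."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhAdjust:
    @pytest.mark.parametrize("n", [1, 7, 100, 1000])
    def test_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        p = rng.uniform(size=n) ** 2
        assert np.allclose(me.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        assert (me.bh_adjust(p) >= p - 1e-15).all()


class TestMethylationLevel:
    def test_pooled_arithmetic(self):
        assert me.methylation_level([C(1, 83, 100)]) == 0.83

    def test_weighted_not_site_averaged(self):
        assert me.methylation_level([C(1, 10, 10), C(2, 0, 90)]) == pytest.approx(0.10)

    def test_zero_coverage_missing(self):
        assert me.methylation_level([C(1, 0, 0)]) is None

    def test_global_equals_coverage_weighted_mean_of_bins(self):
        p = sd.MethylomeSimParams(seed=33)
        recs, _, _ = sd.simulate_methylome(p)
        chrom_sizes = {"chr1": p.span}
        bins = me.binned_levels(recs, chrom_sizes, bin_size=10_000)
        for ctx in ("CG", "CHG", "CHH"):
            sub = bins[(bins["context"] == ctx) & (bins["count_total"] > 0)]
            weighted = (sub["level"] * sub["count_total"]).sum() / sub["count_total"].sum()
            global_level = me.methylation_level([r for r in recs if r.context == ctx])
            assert weighted == pytest.approx(global_level, abs=1e-12)


class TestBinnedLevels:
    def test_empty_bin_is_missing_not_zero(self):
        recs = [C(15_000, 5, 10)]
        out = me.binned_levels(recs, {"chr1": 30_000}, bin_size=10_000)
        cg = out[out["context"] == "CG"].set_index("bin_start")
        assert np.isnan(cg.loc[0, "level"])
        assert cg.loc[10_000, "level"] == 0.5

    def test_single_bin_equals_global(self):
        recs = [C(10, 8, 10), C(500, 0, 10)]
        out = me.binned_levels(recs, {"chr1": 1000}, bin_size=1000)
        cg = out[out["context"] == "CG"]
        assert len(cg) == 1
        assert cg.iloc[0]["level"] == me.methylation_level(recs)

    def test_uniform_simulation_within_three_se(self):
        p = sd.MethylomeSimParams(
            n_sites_per_context={"CG": 5000, "CHG": 0, "CHH": 0}, seed=34
        )
        recs, _, _ = sd.simulate_methylome(p)
        out = me.binned_levels(recs, {"chr1": p.span}, bin_size=25_000)
        cg = out[(out["context"] == "CG") & (out["count_total"] > 0)]
        expected = 0.83 + 0.17 * p.non_conversion
        for _, row in cg.iterrows():
            se = np.sqrt(expected * (1 - expected) / row["count_total"])
            assert row["level"] == pytest.approx(expected, abs=3.5 * se)


def make_gene(gene_id="g1", chrom="chr1", start=4000, end=6000, strand="+",
              exon_bounds=((4000, 4800), (5200, 6000))):
    exons = tuple(Interval(chrom, s, e, strand) for s, e in exon_bounds)
    return GeneModel(gene_id, Interval(chrom, start, end, strand), exons)


class TestGeneMetaprofile:
    def _records_step(self):
        # exonic cytosines at level 0.8, everything else at 0.2
        gene = make_gene()
        recs = []
        for pos0 in range(2000, 8000, 40):  # 0-based placement
            in_exon = any(s <= pos0 < e for s, e in ((4000, 4800), (5200, 6000)))
            m = 8 if in_exon else 2
            recs.append(C(pos0 + 1, m, 10))
        return gene, recs

    def test_step_between_flank_and_exon(self):
        gene, recs = self._records_step()
        prof = me.gene_metaprofile(recs, [gene], flank=2000, n_body_bins=10,
                                   n_flank_bins=5)
        lv = prof.levels["CG"]
        assert all(abs(lv[f"exon_{i}"] - 0.8) < 1e-9 for i in range(1, 11))
        assert all(abs(lv[f"upstream_{i}"] - 0.2) < 1e-9 for i in range(1, 6))
        assert all(abs(lv[f"intron_{i}"] - 0.2) < 1e-9 for i in range(1, 11))

    def test_uniform_methylation_flat_profile(self):
        gene = make_gene()
        recs = [C(p + 1, 5, 10) for p in range(2000, 8000, 50)]
        prof = me.gene_metaprofile(recs, [gene])
        lv = prof.levels["CG"].dropna()
        assert np.allclose(lv, 0.5)

    def test_minus_strand_mirrors_plus(self):
        # mirror-symmetric construction: a plus gene and its reflected minus twin
        L = 10_000
        plus = make_gene("gp", strand="+")
        minus_exons = tuple(
            (L - e, L - s) for s, e in ((4000, 4800), (5200, 6000))
        )[::-1]
        minus = make_gene("gm", strand="-", start=L - 6000, end=L - 4000,
                          exon_bounds=minus_exons)
        rng = np.random.default_rng(35)
        recs_plus, recs_minus = [], []
        for pos0 in range(1500, 8500, 37):
            m = int(rng.integers(0, 11))
            recs_plus.append(C(pos0 + 1, m, 10))
            recs_minus.append(C(L - pos0, m, 10))  # mirrored 1-based position
        prof_p = me.gene_metaprofile(recs_plus, [plus])
        prof_m = me.gene_metaprofile(recs_minus, [minus])
        pd_p = prof_p.levels["CG"]
        pd_m = prof_m.levels["CG"]
        assert np.allclose(pd_p.fillna(-1), pd_m.fillna(-1))

    def test_gene_on_missing_chromosome_skipped(self):
        gene = make_gene(chrom="chrZ")
        prof = me.gene_metaprofile([C(1, 1, 2)], [gene, make_gene("g2")])
        assert prof.levels.attrs["n_skipped"] == 1

    def test_no_genes_errors(self):
        with pytest.raises(ValidationError):
            me.gene_metaprofile([], [])


class TestExpressionVentileGbm:
    def _genes(self, n):
        return [
            make_gene(f"g{i:03d}", start=i * 1000, end=i * 1000 + 500,
                      exon_bounds=((i * 1000, i * 1000 + 500),))
            for i in range(1, n + 1)
        ]

    def test_partition_arithmetic(self):
        genes = self._genes(40)
        expr = [ExpressionRecord(g.gene_id, "s1", float(i))
                for i, g in enumerate(genes)]
        out = me.expression_ventile_gbm([], genes, expr, n_groups=20)
        assert len(out) == 20
        assert (out["n_genes"] == 2).all()

    def test_monotone_planted_trend(self):
        genes = self._genes(40)
        expr = []
        recs = []
        for i, g in enumerate(genes):
            tpm = float(i + 1)
            expr.append(ExpressionRecord(g.gene_id, "s1", tpm))
            level = i / 39  # methylation rises with expression
            m = int(round(level * 100))
            recs.append(C(g.exons[0].start + 10, m, 100))
        out = me.expression_ventile_gbm(recs, genes, expr, n_groups=10)
        assert out["median_tpm"].is_monotonic_increasing
        assert out["level_CG"].is_monotonic_increasing

    def test_all_tied_tpm_stable_order(self):
        genes = self._genes(10)
        expr = [ExpressionRecord(g.gene_id, "s1", 5.0) for g in genes]
        out = me.expression_ventile_gbm([], genes, expr, n_groups=5)
        assert (out["median_tpm"] == 5.0).all()

    def test_too_many_groups_errors(self):
        genes = self._genes(3)
        expr = [ExpressionRecord(g.gene_id, "s1", 1.0) for g in genes]
        with pytest.raises(ValidationError):
            me.expression_ventile_gbm([], genes, expr, n_groups=5)


class TestDetectDmv:
    def test_planted_valley_recovered_with_high_jaccard(self, methylome_dataset):
        _, records, _, truth = methylome_dataset
        dmvs = me.detect_dmv(records)
        assert len(dmvs) == len(truth["dmvs"])
        for planted in truth["dmvs"]:
            jac = max(
                (self._jaccard(planted, d.interval) for d in dmvs), default=0.0
            )
            assert jac >= 0.9

    @staticmethod
    def _jaccard(a, b):
        inter = max(0, min(a.end, b.end) - max(a.start, b.start))
        union = len(a) + len(b) - inter
        return inter / union

    def test_uniform_high_methylation_yields_none(self):
        p = sd.MethylomeSimParams(
            n_sites_per_context={"CG": 3000, "CHG": 3000, "CHH": 0}, seed=36
        )
        recs, _, _ = sd.simulate_methylome(p)
        assert me.detect_dmv(recs) == []

    def test_short_valley_filtered(self):
        p = sd.MethylomeSimParams(
            planted_dmvs=(Interval("chr1", 50_000, 50_500),), seed=37
        )
        recs, _, _ = sd.simulate_methylome(p)
        dmvs = me.detect_dmv(recs, min_length=1000)
        assert all(not d.interval.overlaps(Interval("chr1", 50_000, 50_500))
                   for d in dmvs)

    def test_detected_regions_satisfy_contracts(self, methylome_dataset):
        _, records, _, _ = methylome_dataset
        for d in me.detect_dmv(records):
            assert len(d.interval) >= 1000 and d.n_sites >= 10
            for lv in (d.level_cg, d.level_chg, d.level_chh):
                assert lv is None or lv < 0.05

    def test_bad_threshold_errors(self):
        with pytest.raises(ValidationError):
            me.detect_dmv([], threshold=1.5)


class TestCommonDmvs:
    def test_hand_computed_intersection(self):
        sets = [
            [Interval("chr1", 0, 10_000)],
            [Interval("chr1", 5_000, 15_000)],
            [Interval("chr1", 5_000, 8_000)],
        ]
        assert me.common_dmvs(sets) == [Interval("chr1", 5_000, 8_000)]

    def test_idempotent_on_identical_sets(self):
        ivs = [Interval("chr1", 100, 5000), Interval("chr2", 0, 2000)]
        assert me.common_dmvs([ivs, list(ivs)], min_length=1) == sorted(ivs)

    def test_disjoint_sets_empty(self):
        sets = [[Interval("chr1", 0, 2000)], [Interval("chr1", 3000, 5000)]]
        assert me.common_dmvs(sets) == []

    def test_short_pieces_dropped(self):
        sets = [[Interval("chr1", 0, 2000)], [Interval("chr1", 1500, 5000)]]
        assert me.common_dmvs(sets, min_length=1000) == []

    def test_single_set_errors(self):
        with pytest.raises(ValidationError):
            me.common_dmvs([[Interval("chr1", 0, 10)]])


class TestAnnotateDmvGenes:
    def test_overlap_flags(self):
        dmvs = [Interval("chr1", 1000, 2000)]
        inside = make_gene("inside", start=1200, end=1800,
                           exon_bounds=((1200, 1800),))
        adjacent = make_gene("adjacent", start=2000, end=2500,
                             exon_bounds=((2000, 2500),))
        out = me.annotate_dmv_genes(dmvs, [inside, adjacent])
        flags = dict(zip(out["gene_id"], out["in_dmv"]))
        assert flags == {"inside": True, "adjacent": False}

    def test_planted_overlap_count(self):
        dmv = [Interval("chr1", 10_000, 40_000)]
        genes = [
            make_gene(f"g{i}", start=i * 10_000, end=i * 10_000 + 5000,
                      exon_bounds=((i * 10_000, i * 10_000 + 5000),))
            for i in range(10)
        ]
        out = me.annotate_dmv_genes(dmv, genes)
        assert out["in_dmv"].sum() == 3  # genes at 10k, 20k, 30k


class TestEnrichmentChi2:
    def test_hand_computed_table(self):
        chi2, dof, p = me.enrichment_chi2(50, 50, 10, 90)
        assert chi2 == pytest.approx(38.095, abs=0.001)
        assert dof == 1 and p < 1e-4

    def test_independent_table_zero(self):
        chi2, _, p = me.enrichment_chi2(20, 80, 10, 40)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValidationError):
            me.enrichment_chi2(0, 0, 5, 5)
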