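"""Windowed density comparison, regression, classification, heterozygosity."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from svpopgen.landscape import (
    bin_counts,
    classify_breakends,
    density_regression,
    individual_heterozygosity,
    overlap_by_size_class,
    repeat_fraction,
    subtelomere_enrichment,
    window_is_subtelomeric,
)
from svpopgen.vcfio import MISSING, VariantRecord
from tests.conftest import make_matrix

LENGTHS = {"chr1": 3_000_000, "chr2": 1_500_000}


def sv(pos, typ="DEL", length=300, chrom="chr1", vid=None):
    end = pos + length - 1 if typ in ("DEL", "DUP", "INV") else None
    return VariantRecord(chrom, pos, typ, {}, end=end,
                         length=None if typ == "TRA" else length,
                         strands="+-", variant_id=vid or f"{typ}{pos}")


class TestBinCounts:
    def test_snp_bin_assignment(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [1_500_000]})
        w = bin_counts(snps, [], LENGTHS)
        hit = w[(w["chrom"] == "chr1") & (w["start"] == 1_000_000)]
        assert hit["snp_count"].item() == 1
        assert w["snp_count"].sum() == 1

    def test_sv_coverage_semantics_spans_two_bins(self):
        rec = sv(999_900, length=301)  # 999,900..1,000,200 crosses the bin edge
        w = bin_counts(pd.DataFrame({"chrom": [], "pos": []}), [rec], LENGTHS)
        counted = w[(w["chrom"] == "chr1") & (w["sv_count"] > 0)]
        assert list(counted["start"]) == [0, 1_000_000]
        assert w["sv_count"].sum() == 2  # coverage count exceeds record count

    def test_tra_counted_at_breakend_only(self):
        rec = sv(999_990, typ="TRA")
        w = bin_counts(pd.DataFrame({"chrom": [], "pos": []}), [rec], LENGTHS)
        assert w["sv_count"].sum() == 1

    def test_empty_chromosome_all_zero(self):
        w = bin_counts(pd.DataFrame({"chrom": [], "pos": []}), [], LENGTHS)
        assert (w["snp_count"] == 0).all() and (w["sv_count"] == 0).all()

    def test_snp_conservation(self):
        rng = np.random.default_rng(0)
        snps = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 500),
            "pos": rng.integers(1, 1_400_000, 500),
        })
        w = bin_counts(snps, [], LENGTHS)
        assert w["snp_count"].sum() == 500


class TestRegression:
    def test_intercept_only_fit_equals_mean(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(7.0, 200)
        windows = pd.DataFrame({"chrom": "chr1", "start": 0, "end": 1,
                                "snp_count": 5, "sv_count": y})
        reg = density_regression(windows)
        assert np.allclose(reg.fitted, y.mean(), atol=1e-8)

    def test_slope_recovery_within_three_se(self):
        rng = np.random.default_rng(2)
        x = rng.integers(500, 5000, size=500).astype(float)
        b, a = 0.001, 0.5
        y = rng.poisson(np.exp(a + b * x))
        reg = density_regression(pd.DataFrame({"snp_count": x, "sv_count": y}))
        se = b / max(reg.t_value, 1e-9) * (reg.slope / b)
        assert abs(reg.slope - b) < 3 * abs(reg.slope / reg.t_value)

    def test_perfect_fit_zero_deviance_residuals(self):
        # two distinct design points: the 2-parameter fit passes through exactly
        x = np.repeat([10.0, 20.0], 10)
        y = np.repeat([2.0, 8.0], 10)
        reg = density_regression(pd.DataFrame({"snp_count": x, "sv_count": y}))
        assert np.allclose(reg.residuals, 0.0, atol=1e-6)

    def test_all_zero_svs_degenerate(self):
        reg = density_regression(pd.DataFrame({"snp_count": np.arange(20) + 1.0,
                                               "sv_count": np.zeros(20)}))
        assert reg.degenerate and (reg.residuals <= 0).all()

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            density_regression(pd.DataFrame({"snp_count": [1] * 5, "sv_count": [1] * 5}))

    def test_null_slope_t_calibrated(self):
        """Independent SNP/SV counts: |t| < 3 in >= 95% of replicates."""
        rng = np.random.default_rng(3)
        n_big = 0
        reps = 200
        for _ in range(reps):
            x = rng.poisson(2000, 150).astype(float)
            y = rng.poisson(15, 150).astype(float)
            reg = density_regression(pd.DataFrame({"snp_count": x, "sv_count": y}))
            if abs(reg.t_value) >= 3:
                n_big += 1
        assert n_big / reps <= 0.05


class TestSubtelomereEnrichment:
    def test_flags_follow_fraction(self):
        w = bin_counts(pd.DataFrame({"chrom": [], "pos": []}), [], LENGTHS)
        flags = window_is_subtelomeric(w, LENGTHS, 0.1)
        chr1 = w["chrom"] == "chr1"
        # chr1: 3 Mb, terminal windows 300 kb -> first and last 1-Mb bins overlap
        assert flags[np.flatnonzero(chr1)[0]] and flags[np.flatnonzero(chr1)[-1]]

    def test_all_subtelomeric_summary_omitted(self):
        w = bin_counts(pd.DataFrame({"chrom": [], "pos": []}), [], {"chr1": 2_000_000})
        res = subtelomere_enrichment(w, np.zeros(len(w)), {"chr1": 2_000_000}, 0.49)
        assert res is None

    def test_planted_enrichment_detected(self):
        lengths = {"chr1": 10_000_000, "chr2": 8_000_000}
        w = bin_counts(pd.DataFrame({"chrom": [], "pos": []}), [], lengths)
        sub = window_is_subtelomeric(w, lengths, 0.05)
        resid = np.where(sub, 2.0, -0.5) + np.random.default_rng(4).normal(0, 0.2, len(w))
        res = subtelomere_enrichment(w, resid, lengths, 0.05)
        assert res["difference"] > 0 and res["p_value"] < 0.05


class TestSizeClasses:
    GENES = pd.DataFrame({"chrom": ["chr1"] * 3,
                          "start": [10_000, 20_000, 30_000],
                          "end": [15_000, 25_000, 35_000],
                          "feature_id": ["g1", "g2", "g3"]})

    def test_classification_and_row_sums(self):
        recs = [
            VariantRecord("chr1", 12_000, "SNP", {}, length=1),  # inside g1
            sv(9_000, length=50),  # 0 genes
            sv(9_990, length=50_000),  # spans all three genes
            sv(19_000, length=2_000),  # overlaps g2 only
        ]
        table = overlap_by_size_class(recs, self.GENES)
        by = {r.size_class: r for r in table.itertuples()}
        assert by["1 bp"].prop_1_gene == 1.0
        assert by["30-99 bp"].prop_0_genes == 1.0
        assert by[">=10 kb"].prop_2plus_genes == 1.0
        assert by["1-10 kb"].prop_1_gene == 1.0
        sums = table[["prop_0_genes", "prop_1_gene", "prop_2plus_genes"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_tra_excluded_from_size_classes(self):
        table = overlap_by_size_class([sv(12_000, typ="TRA")], self.GENES)
        assert len(table) == 0


class TestBreakendClassification:
    REPEATS = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [10_000, 10_020, 50_000],
        "end": [10_019, 10_100, 50_200],
        "feature_id": ["simple", "LINE", "LTR"],
    })

    def test_largest_overlap_wins(self):
        # window [9999, 10029): 20 bp of 'simple', 9 bp of 'LINE'
        rec = sv(10_000, length=500)
        got = classify_breakends([rec], self.REPEATS, LENGTHS)
        assert got["repeat_class"][0] == "simple"

    def test_no_repeat_within_window_none(self):
        got = classify_breakends([sv(200_000)], self.REPEATS, LENGTHS)
        assert got["repeat_class"][0] == "none"

    def test_breakend_inside_ltr(self):
        got = classify_breakends([sv(50_100, typ="TRA")], self.REPEATS, LENGTHS)
        assert got["repeat_class"][0] == "LTR"

    def test_window_truncated_at_chromosome_end(self):
        rec = sv(2_999_990, typ="TRA", chrom="chr1")
        got = classify_breakends([rec], self.REPEATS, LENGTHS)
        assert got["repeat_class"][0] == "none"

    def test_repeat_fraction(self):
        got = classify_breakends([sv(10_000), sv(200_000)], self.REPEATS, LENGTHS)
        assert repeat_fraction(got) == pytest.approx(0.5)


class TestIndividualHeterozygosity:
    def test_all_het_sample_is_one(self):
        m = make_matrix([[1, 0], [1, 2], [1, MISSING]])
        table, _ = individual_heterozygosity(m)
        assert table["het_proportion"][0] == pytest.approx(1.0)
        assert table["het_proportion"][1] == pytest.approx(0.0)  # [0, 2, missing]

    def test_uncalled_sample_nan(self):
        m = make_matrix([[MISSING, 1], [MISSING, 0]])
        table, _ = individual_heterozygosity(m)
        assert np.isnan(table["het_proportion"][0])

    def test_batch_dropout_depresses_sv_heterozygosity(self):
        """Designed dropout in one batch lowers that batch's SV het rate."""
        from svpopgen.merge import MergeParams, merge_across_samples, merge_per_sample
        from svpopgen.simulate import SimConfig, Simulation, identity_profiles
        from svpopgen.vcfio import build_matrix

        cfg = SimConfig(seed=21, n_snps=50, n_svs=120,
                        caller_profiles=identity_profiles(),
                        batch_sv_dropout={"b2": 0.5})
        _, truth, calls = Simulation(cfg).run()
        per = {}
        for sample in truth.samples["sample"]:
            callsets = [calls[(sample, p.name)] for p in cfg.caller_profiles]
            per[sample] = merge_per_sample(callsets, MergeParams(), sample=sample)
        cohort = merge_across_samples(per)
        m = build_matrix([c.to_record() for c in cohort], truth.population_map())
        table, test = individual_heterozygosity(m)
        by_batch = table.groupby("batch")["het_proportion"].mean()
        assert by_batch["b2"] < by_batch["b1"]
        assert test["p_value"] < 0.05
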