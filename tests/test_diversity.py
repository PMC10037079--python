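"""Diversity estimators, invader-specific extraction, SFS, PCA."""

import numpy as np
import pandas as pd
import pytest

from svpopgen.diversity import (
    classify_gene_overlap,
    common_filter,
    diversity,
    folded_sfs,
    invader_specific,
    pca,
)
from svpopgen.simulate import SimConfig, _balding_nichols, _rng
from svpopgen.vcfio import MISSING, VariantRecord
from tests.conftest import make_matrix


class TestDiversityTable:
    def test_pi_formula_small_sample(self):
        """n=4 alleles, j=2: pi = 2*2*2/(4*3) = 2/3, checked by pair enumeration."""
        m = make_matrix([[1, 1]])  # two samples, both het
        t = diversity(m)
        # enumeration oracle: alleles (1,0,1,0); 4 of the 6 pairs differ
        alleles = [1, 0, 1, 0]
        diffs = sum(a != b for i, a in enumerate(alleles) for b in alleles[i + 1:])
        assert t["pi"][0] == pytest.approx(diffs / 6)
        assert t["pi"][0] == pytest.approx(2 / 3)

    def test_he_large_sample_limit(self):
        d = np.array([[1] * 200])  # p = 0.5 with 400 alleles
        t = diversity(make_matrix(d))
        assert t["H_E"][0] == pytest.approx(0.5)
        assert t["pi"][0] == pytest.approx(0.5, abs=2e-3)

    def test_monomorphic_site_zeroes(self):
        t = diversity(make_matrix([[0, 0, 0]]))
        assert t["H_O"][0] == 0 and t["H_E"][0] == 0 and t["pi"][0] == 0

    def test_pi_he_identity_per_site(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(50, 12))
        d[rng.random(d.shape) < 0.15] = MISSING
        m = make_matrix(d)
        j, n = m.allele_counts()
        ok = n > 1
        p = j[ok] / n[ok]
        he = 1 - p**2 - (1 - p) ** 2
        pi = 2 * j[ok] * (n[ok] - j[ok]) / (n[ok] * (n[ok] - 1))
        assert np.allclose(pi, he * n[ok] / (n[ok] - 1))

    def test_bottleneck_population_less_diverse(self):
        rng = _rng(13, "divtest")
        n_loci = 3000
        p = rng.uniform(0.05, 0.95, n_loci)
        f_src, f_bot = 0.02, 0.4
        p_src = _balding_nichols(rng, p, f_src)
        p_bot = _balding_nichols(rng, p, f_bot)
        d_src = rng.binomial(2, p_src[:, None], size=(n_loci, 12))
        d_bot = rng.binomial(2, p_bot[:, None], size=(n_loci, 12))
        m = make_matrix(np.hstack([d_src, d_bot]),
                        populations=["SRC"] * 12 + ["BOT"] * 12)
        t = diversity(m).set_index("population")
        pi_src, pi_bot = t.loc["SRC", "pi"], t.loc["BOT", "pi"]
        expected_ratio = (1 - f_bot) / (1 - f_src)
        mc_se = pi_src / np.sqrt(n_loci)  # conservative scale for the contrast
        assert pi_bot < pi_src
        assert abs(pi_bot - expected_ratio * pi_src) < 3 * mc_se + 0.01

    def test_private_alleles_disjoint_and_counted(self):
        # site 0: alt only in A; site 1: alt only in B; site 2: shared
        d = [[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 1, 1]]
        m = make_matrix(d, populations=["A", "A", "B", "B"])
        t = diversity(m).set_index("population")
        assert t.loc["A", "private_alleles"] == 1
        assert t.loc["B", "private_alleles"] == 1


class TestInvaderSpecific:
    def test_basic_extraction_and_exclusion(self):
        pops = ["NAT", "NAT", "INV", "INV", "EDGE"]
        d = [
            [0, 0, 1, 0, 0],  # invader-specific
            [1, 0, 1, 1, 0],  # present in native
            [0, 0, 0, 0, 2],  # only in excluded range-edge deme
        ]
        m = make_matrix(d, populations=pops)
        got = invader_specific(m, ["INV"], excluded_samples=["s4"])
        assert got == ["v0"]

    def test_single_native_copy_excludes(self):
        d = [[1, 0, 2, 2, 2]]
        m = make_matrix(d, populations=["NAT", "NAT", "INV", "INV", "INV"])
        assert invader_specific(m, ["INV"]) == []

    def test_truth_recovery_end_to_end(self, identity_study):
        from svpopgen.merge import MergeParams, merge_across_samples, merge_per_sample
        from svpopgen.vcfio import build_matrix

        cfg, (genome, truth, calls) = identity_study
        per = {}
        for sample in truth.samples["sample"]:
            callsets = [calls[(sample, p.name)] for p in cfg.caller_profiles]
            per[sample] = merge_per_sample(callsets, MergeParams(), sample=sample)
        cohort = merge_across_samples(per)
        m = build_matrix([c.to_record() for c in cohort], truth.population_map())
        excluded = list(truth.samples.loc[truth.samples["role"] == "range_edge", "sample"])
        got = invader_specific(m, ["NA", "AU_EAST", "AU_SOUTH"], excluded)
        # cohort ids are positional; map back to truth ids by (chrom, pos)
        key = {(r.chrom, r.pos): i for i, r in truth.svs.iterrows()}
        got_truth_ids = {
            truth.svs["id"].iloc[key[(row.chrom, row.pos)]]
            for row in m.sites.itertuples() if row.id in set(got)
        }
        want = set(truth.svs.loc[truth.svs["invader_specific"], "id"])
        assert got_truth_ids == want


class TestCommonFilter:
    def test_strictly_greater_boundary(self):
        # 10 samples = 20 alleles: 3 alt -> 0.15 exactly; 4 alt -> 0.2
        edge = [1, 1, 1] + [0] * 7
        common = [1, 1, 1, 1] + [0] * 6
        m = make_matrix([edge, common])
        got = common_filter(["v0", "v1"], m)
        assert got == ["v1"]

    def test_empty_input(self):
        m = make_matrix([[1, 0]])
        assert common_filter([], m) == []


class TestSfs:
    GENES = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [12_000],
                          "feature_id": ["g1"]})

    def test_gene_overlap_classes(self):
        recs = [
            VariantRecord("chr1", 9_000, "DEL", {}, end=13_000, length=4001,
                          strands="+-", variant_id="a"),  # contains the gene
            VariantRecord("chr1", 11_000, "DEL", {}, end=14_000, length=3001,
                          strands="+-", variant_id="b"),  # break end inside
            VariantRecord("chr1", 50_000, "DEL", {}, end=50_100, length=101,
                          strands="+-", variant_id="c"),  # far away
        ]
        assert classify_gene_overlap(recs, self.GENES) == [
            "complete_overlap", "breakend_overlap", "no_overlap"]

    def test_folding_and_top_bin(self):
        # frequencies: 0.9 alt -> folded 0.1 (bin 0.05-0.10); 0.5 -> top bin
        d = [[2, 2, 2, 2, 1], [1, 1, 1, 2, 0]]
        m = make_matrix(d)
        sfs = folded_sfs(m)
        hist = sfs.set_index("bin_low")["count"]
        assert hist[0.05] == 1  # folded 0.1 falls in (0.05, 0.10]
        assert hist[0.45] == 1  # folded 0.5 counted once in the top bin

    def test_histograms_sum_to_class_sizes(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(60, 10))
        labels = list(rng.choice(["no_overlap", "breakend_overlap", "complete_overlap"], 60))
        sfs = folded_sfs(make_matrix(d), labels)
        for cls in set(labels):
            total = sfs.loc[sfs["class"] == cls, "count"].sum()
            assert total == labels.count(cls)


class TestPca:
    def test_duplicate_samples_identical_coordinates(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(200, 6))
        d[:, 5] = d[:, 4]
        res = pca(make_matrix(d))
        c = res.coordinates
        a = c.loc[c["sample"] == "s4", [f"PC{i}" for i in range(1, 4)]].to_numpy()
        b = c.loc[c["sample"] == "s5", [f"PC{i}" for i in range(1, 4)]].to_numpy()
        assert np.allclose(a, b, atol=1e-8)

    def test_two_populations_separate_on_pc1(self):
        rng = _rng(17, "pcatest")
        n_loci, n_per = 3000, 25
        p = rng.uniform(0.1, 0.9, n_loci)
        pa = _balding_nichols(rng, p, 0.1)
        pb = _balding_nichols(rng, p, 0.1)
        d = np.hstack([
            rng.binomial(2, pa[:, None], size=(n_loci, n_per)),
            rng.binomial(2, pb[:, None], size=(n_loci, n_per)),
        ])
        res = pca(make_matrix(d, populations=["A"] * n_per + ["B"] * n_per))
        pc1 = res.coordinates["PC1"].to_numpy()
        threshold = (pc1[:n_per].mean() + pc1[n_per:].mean()) / 2
        side_a = pc1[:n_per] > threshold
        side_b = pc1[n_per:] > threshold
        assert side_a.all() != side_b.all() and len(set(side_a)) == 1 and len(set(side_b)) == 1

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(100, 8))
        r1 = pca(make_matrix(d))
        r2 = pca(make_matrix(d.copy()))
        assert np.allclose(r1.coordinates["PC1"], r2.coordinates["PC1"])

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            pca(make_matrix([[0, 0, 0], [2, 2, 2]]))


def test_admixed_invader_sv_diversity_reversal():
    """Bottlenecked invader: lower SNP pi; admixed SV input: SV pi >= source."""
    from svpopgen.simulate import Simulation
    from svpopgen.vcfio import build_matrix

    cfg = SimConfig(seed=31, n_snps=4000, n_svs=250, sv_invader_admixture=True,
                    invader_specific_sv_frac=0.0)
    _, truth, _ = Simulation(cfg).run()
    popmap = truth.population_map()
    snp_m = build_matrix(truth.snp_records(), popmap)
    sv_m = build_matrix(truth.sv_records(), popmap)
    snp_t = diversity(snp_m).set_index("population")
    sv_t = diversity(sv_m).set_index("population")
    mc = snp_t.loc["UK", "pi"] / np.sqrt(cfg.n_snps)
    assert snp_t.loc["AU_EAST", "pi"] < snp_t.loc["UK", "pi"] + 3 * mc
    assert snp_t.loc["AU_EAST", "pi"] < snp_t.loc["UK", "pi"]
    mc_sv = sv_t.loc["UK", "pi"] / np.sqrt(cfg.n_svs)
    assert sv_t.loc["AU_EAST", "pi"] >= sv_t.loc["UK", "pi"] - 3 * mc_sv
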