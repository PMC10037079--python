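"""F_ST + POD calibration, beta(1) scan, pseudo-beta, group comparison."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from svpopgen.selection import (
    _beta_normalizers,
    beta_kernel,
    beta_scan,
    dunn_test,
    fst_per_locus,
    group_comparison,
    multilocus_fst,
    pod_threshold,
    pseudo_beta,
    seven_groups,
    trimmed_mean,
)
from svpopgen.vcfio import VariantRecord
from tests.conftest import make_matrix


def wc_theta_oracle(geno1, geno2):
    """Independent per-locus Weir-Cockerham (1984) theta, scalar textbook form."""
    thetas = []
    for row1, row2 in zip(geno1, geno2):
        r = 2
        ns = [len(row1), len(row2)]
        ps = [sum(row1) / (2 * len(row1)), sum(row2) / (2 * len(row2))]
        hs = [sum(1 for g in row1 if g == 1) / len(row1),
              sum(1 for g in row2 if g == 1) / len(row2)]
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        thetas.append(np.nan if (a + b + c) == 0 else a / (a + b + c))
    return np.array(thetas)


class TestFst:
    def test_fixed_difference_is_one(self):
        d = [[0] * 10 + [2] * 10]
        m = make_matrix(d, populations=["A"] * 10 + ["B"] * 10)
        theta = fst_per_locus(m, np.arange(10), np.arange(10, 20))
        assert theta[0] == pytest.approx(1.0)

    def test_equal_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.5, size=(300, 60))
        m = make_matrix(d, populations=["A"] * 30 + ["B"] * 30)
        theta = fst_per_locus(m, np.arange(30), np.arange(30, 60))
        assert abs(np.nanmean(theta)) < 0.02

    def test_monomorphic_locus_undefined(self):
        m = make_matrix([[0, 0, 0, 0]], populations=["A", "A", "B", "B"])
        assert np.isnan(fst_per_locus(m, np.arange(2), np.arange(2, 4))[0])

    def test_matches_independent_textbook_oracle(self):
        rng = np.random.default_rng(1)
        n = 50
        g1 = rng.binomial(2, 0.2, size=(40, n))
        g2 = rng.binomial(2, 0.8, size=(40, n))
        m = make_matrix(np.hstack([g1, g2]), populations=["A"] * n + ["B"] * n)
        got = fst_per_locus(m, np.arange(n), np.arange(n, 2 * n))
        want = wc_theta_oracle(g1.tolist(), g2.tolist())
        assert np.allclose(got, want, atol=1e-10, equal_nan=True)


class TestPodThreshold:
    @staticmethod
    def _neutral_matrix(rng, n_loci, n_per_group, fst=0.05):
        p = rng.uniform(0.05, 0.95, n_loci)
        a = p * (1 - fst) / fst
        b = (1 - p) * (1 - fst) / fst
        d = np.hstack([
            rng.binomial(2, rng.beta(a, b)[:, None], size=(n_loci, n_per_group)),
            rng.binomial(2, rng.beta(a, b)[:, None], size=(n_loci, n_per_group)),
        ])
        return make_matrix(d, populations=["A"] * n_per_group + ["B"] * n_per_group)

    def test_same_seed_same_threshold(self):
        rng = np.random.default_rng(2)
        m = self._neutral_matrix(rng, 500, 12)
        g1, g2 = np.arange(12), np.arange(12, 24)
        t1 = pod_threshold(m, g1, g2, n_pod=1000, seed=5).threshold
        t2 = pod_threshold(m, g1, g2, n_pod=1000, seed=5).threshold
        assert t1 == t2
        assert t1 != pod_threshold(m, g1, g2, n_pod=1000, seed=6).threshold

    def test_neutral_flagged_fraction_near_nominal(self):
        """Mean flagged fraction over independent neutral datasets ~ 1%.

        Pooling over datasets averages out the Monte-Carlo noise of each
        5,000-locus empirical threshold, which dominates single-dataset runs.
        """
        rng = np.random.default_rng(3)
        fracs = []
        for s in range(4):
            m = self._neutral_matrix(rng, 5000, 24)
            scan = pod_threshold(m, np.arange(24), np.arange(24, 48), seed=s)
            fracs.append(scan.flags.mean())
        assert 0.006 <= np.mean(fracs) <= 0.014

    def test_planted_divergent_loci_flagged(self):
        rng = np.random.default_rng(4)
        n_per = 24
        m = self._neutral_matrix(rng, 2000, n_per)
        planted = rng.choice(2000, size=20, replace=False)
        d = m.dosages.copy()
        d[planted, :n_per] = rng.binomial(2, 0.1, size=(20, n_per))
        d[planted, n_per:] = rng.binomial(2, 0.85, size=(20, n_per))
        m2 = make_matrix(d, populations=["A"] * n_per + ["B"] * n_per)
        scan = pod_threshold(m2, np.arange(n_per), np.arange(n_per, 2 * n_per), seed=2)
        assert scan.flags[planted].mean() >= 0.8


class TestBetaScan:
    def test_empty_window_scores_zero(self):
        # single polymorphic site well away from others
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.4, size=(3, 10))
        m = make_matrix(d, positions=[10_000, 50_000, 90_000])
        out = beta_scan(m)
        assert (out["S"] == 0).all() and (out["beta"] == 0).all()

    def test_core_maf_filter(self):
        d = np.array([[1] + [0] * 9, [1, 1, 1, 1] + [0] * 6])  # MAF 0.05 and 0.2
        m = make_matrix(d, positions=[1000, 1500])
        out = beta_scan(m)
        assert list(out["f_core"]) == [0.2]

    def test_refuses_tiny_sample(self):
        with pytest.raises(ValueError):
            beta_scan(make_matrix([[1]]))

    def test_neutral_window_counts_give_zero_beta(self):
        """Window with site counts proportional to the neutral folded expectation
        has theta_beta = theta_W by construction of the normalizer."""
        n = 20
        f_core = 0.4
        ks = np.arange(1, n // 2 + 1)
        c_nk = (1.0 / ks + 1.0 / (n - ks)) / (1.0 + (ks == n - ks))
        for mlt in (10, 100, 1000):
            counts = mlt * c_nk  # exact proportionality (fractional counts)
            a_n, m_max, b_n = _beta_normalizers(n, f_core)
            theta_b = np.sum(counts * beta_kernel(ks / n, f_core, m_max)) / b_n
            theta_w = counts.sum() / a_n
            assert theta_b == pytest.approx(theta_w, rel=1e-9)

    def test_integer_rounded_neutral_counts_converge(self):
        n = 20
        f_core = 0.35
        ks = np.arange(1, n // 2 + 1)
        c_nk = (1.0 / ks + 1.0 / (n - ks)) / (1.0 + (ks == n - ks))
        rel_err = []
        for mlt in (20, 200, 2000):
            counts = np.round(mlt * c_nk)
            a_n, m_max, b_n = _beta_normalizers(n, f_core)
            theta_b = np.sum(counts * beta_kernel(ks / n, f_core, m_max)) / b_n
            theta_w = counts.sum() / a_n
            rel_err.append(abs(theta_b - theta_w) / theta_w)
        assert rel_err[-1] < rel_err[0] and rel_err[-1] < 0.01

    def test_planted_cluster_scores_above_neutral(self):
        """A frequency-matched cluster around the core lifts beta above 0."""
        rng = np.random.default_rng(6)
        n_samp = 10
        # neutral backdrop: scattered sites at random folded frequencies
        pos = [int(p) for p in np.arange(50) * 3000 + 10_000]
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 50)[:, None], size=(50, n_samp))
        # planted cluster at 500k: core + 12 companions at folded ~0.4 within 1 kb
        cpos = [500_000] + [500_000 + o for o in range(-600, 700, 100) if o != 0]
        freqs = np.clip(0.4 + rng.uniform(-0.04, 0.04, len(cpos)), 0, 0.5)
        dc = rng.binomial(2, freqs[:, None], size=(len(cpos), n_samp))
        all_pos = pos + cpos
        allд = np.vstack([d, dc])
        order = np.argsort(all_pos)
        m = make_matrix(allд[order], positions=np.array(all_pos)[order])
        out = beta_scan(m)
        near = out[(out["pos"] - 500_000).abs() <= 1000]
        far = out[(out["pos"] - 500_000).abs() > 2000]
        assert near["beta"].median() > max(0.0, far["beta"].median())


class TestTrimmedMean:
    @pytest.mark.parametrize("k", [1, 10, 20, 100])
    def test_floor_rule_against_direct_arithmetic(self, k):
        rng = np.random.default_rng(k)
        scores = rng.normal(size=k)
        t = int(np.floor(0.05 * k))
        expected = np.sort(scores)[t:k - t].mean()
        assert trimmed_mean(scores) == pytest.approx(expected)

    def test_spec_example_no_trim_at_k10(self):
        scores = [0, 1, 2, 3, 4, 5, 6, 7, 8, 100]
        assert trimmed_mean(np.array(scores)) == pytest.approx(13.6)
        doubled = np.array(scores * 2)
        t = 1  # floor(0.05 * 20)
        expected = np.sort(doubled)[t:-t].mean()
        assert trimmed_mean(doubled) == pytest.approx(expected)

    def test_constant_scores(self):
        for k in (1, 5, 40):
            assert trimmed_mean(np.full(k, 3.25)) == pytest.approx(3.25)


class TestPseudoBeta:
    BETA = pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "pos": [9_000, 9_500, 10_000, 10_500],
        "beta": [1.0, 2.0, 4.0, 8.0],
    })

    def _sv(self, pos):
        return VariantRecord("chr1", pos, "DEL", {}, end=pos + 499, length=500,
                             strands="+-", variant_id=f"sv{pos}")

    def test_half_open_window_boundaries(self):
        # break end at 10,000: window [9,000, 10,000) includes 9,000 and 9,500
        out = pseudo_beta([self._sv(10_000)], self.BETA)
        assert out["k"][0] == 2
        assert out["pseudo_beta"][0] == pytest.approx(1.5)

    def test_snp_at_breakend_excluded(self):
        out = pseudo_beta([self._sv(10_500)], self.BETA)
        # window [9,500, 10,500): includes 9,500 and 10,000, excludes 10,500
        assert out["k"][0] == 2
        assert out["pseudo_beta"][0] == pytest.approx(3.0)

    def test_no_upstream_snps_nan(self):
        out = pseudo_beta([self._sv(5_000)], self.BETA)
        assert out["k"][0] == 0 and np.isnan(out["pseudo_beta"][0])

    def test_pooled_mode_emits_raw_scores(self):
        out = pseudo_beta([self._sv(10_000)], self.BETA, mode="pooled")
        assert list(out["pseudo_beta"]) == [1.0, 2.0]

    def test_trimmed_equals_pooled_mean_when_no_trim(self):
        rng = np.random.default_rng(8)
        beta = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.sort(rng.choice(np.arange(9_100, 10_000), 15, replace=False)),
            "beta": rng.normal(size=15),
        })
        sv = self._sv(10_000)
        per = pseudo_beta([sv], beta)  # k=15 < 20 -> no values trimmed
        pooled = pseudo_beta([sv], beta, mode="pooled")
        assert per["pseudo_beta"][0] == pytest.approx(pooled["pseudo_beta"].mean())


class TestGroupComparison:
    def test_identical_constant_groups_h_zero(self):
        groups = {"a": np.full(5, 2.0), "b": np.full(7, 2.0)}
        res = group_comparison(groups)
        assert res.H == 0.0 and res.p_value == 1.0

    def test_small_groups_dropped(self):
        groups = {"a": np.arange(10.0), "b": np.arange(10.0) + 1, "tiny": np.array([1.0])}
        res = group_comparison(groups)
        assert res.dropped == ["tiny"] and res.df == 1

    def test_too_few_groups_refused(self):
        with pytest.raises(ValueError):
            group_comparison({"a": np.arange(5.0), "tiny": np.array([1.0])})

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(9)
        groups = {f"g{i}": rng.normal(0, 1, 100) for i in range(6)}
        groups["shifted"] = rng.normal(2, 1, 100)
        res = group_comparison(groups)
        assert res.p_value < 1e-6
        dunn = res.dunn
        vs = dunn[(dunn["group_i"] == "shifted") | (dunn["group_j"] == "shifted")]
        assert (vs["p_adjusted"] < 0.05).all()

    def test_dunn_matches_kruskal_for_two_groups(self):
        rng = np.random.default_rng(10)
        g = {"a": rng.normal(0, 1, 30), "b": rng.normal(0.5, 1, 30)}
        z = dunn_test(g)["z"][0]
        H, _ = scipy.stats.kruskal(g["a"], g["b"])
        assert z**2 == pytest.approx(H, rel=1e-9)

    def test_seven_group_assembly_partitions(self):
        beta = pd.DataFrame({"id": [f"s{i}" for i in range(6)],
                             "beta": np.arange(6.0)})
        pseudo = pd.DataFrame({
            "sv_id": [f"v{i}" for i in range(5)],
            "sv_type": ["DEL", "DUP", "TRA", "INV", "DEL"],
            "k": [3, 3, 3, 3, 0],
            "pseudo_beta": [0.1, 0.2, 0.3, 0.4, np.nan],
        })
        groups = seven_groups(beta, {"s0"}, pseudo, {"v0"})
        assert len(groups) == 7
        total = sum(len(v) for v in groups.values())
        assert total == 6 + 4  # k=0 SV excluded; every scored variant in one group
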