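"""Selection scans: differentiation outliers and balancing-selection scores.

Directional selection is screened with per-locus Weir–Cockerham F_ST between
a native and an invasive group, thresholded empirically: a pseudo-observed
dataset (POD) of neutral loci is simulated under a Balding–Nichols null
fitted to the data (multi-locus F_ST, observed allele-frequency spectrum and
sample sizes), and the scan's threshold is the 99th percentile of the
simulated statistic, so a fully neutral dataset flags ~1% of loci by
construction.

Balancing selection is scored within the native population with a folded
beta(1) statistic: for a core SNP at folded frequency ``f_c``, nearby SNPs at
similar folded frequencies are up-weighted by a similarity kernel ``g`` into
a frequency-weighted diversity estimator ``theta_beta``, which is compared
with Watterson's ``theta_W`` from the same window; ``beta(1) = theta_beta -
theta_W`` is positive when the window holds an excess of SNPs at frequencies
close to the core's.  The kernel normalizer is chosen so that
``E[theta_beta] = theta`` under the neutral folded frequency expectation,
making beta(1) mean-zero on neutral data by construction.

SVs cannot be scored directly (the statistic needs dense SNPs), so each SV
receives a pseudo-beta(1): the trimmed mean (0.1 trimming, middle 90%) of
SNP beta(1) scores within the 1,000 bp immediately upstream of its first
break end — the same distance bound used for consensus merging — with a
pooled alternative that keeps the raw upstream scores per SV group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from svpopgen.vcfio import GenotypeMatrix, VariantRecord


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(matrix: GenotypeMatrix, groups: list[np.ndarray]):
    """Per-locus variance components (a, b, c) of the WC (1984) estimator."""
    r = len(groups)
    n_i, p_i, h_i = [], [], []
    for idx in groups:
        d = matrix.dosages[:, idx]
        called = (d >= 0).sum(axis=1).astype(float)
        j = np.where(d >= 0, d, 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, j / np.maximum(2 * called, 1), np.nan)
            h = np.where(called > 0, (d == 1).sum(axis=1) / np.maximum(called, 1), np.nan)
        n_i.append(called)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)  # r x loci, individuals genotyped
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    n_bar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    return a, b, c, p_bar


def fst_per_locus(matrix: GenotypeMatrix, group1: np.ndarray, group2: np.ndarray) -> np.ndarray:
    """Weir-Cockerham theta per biallelic locus between two sample groups.

    Loci monomorphic across both groups are undefined (NaN).  Raw values are
    returned (may be negative); floor at 0 for thresholding.
    """
    a, b, c, p_bar = _wc_components(matrix, [np.asarray(group1), np.asarray(group2)])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    theta = np.where((p_bar <= 0) | (p_bar >= 1), np.nan, theta)
    return theta


def multilocus_fst(matrix: GenotypeMatrix, group1: np.ndarray, group2: np.ndarray) -> float:
    """Multi-locus WC estimate: ratio of summed components."""
    a, b, c, p_bar = _wc_components(matrix, [np.asarray(group1), np.asarray(group2)])
    ok = np.isfinite(a + b + c) & (p_bar > 0) & (p_bar < 1)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    return float(a[ok].sum() / denom) if denom > 0 else float("nan")


@dataclass
class OutlierScan:
    statistic: np.ndarray  # raw per-locus theta (NaN where undefined)
    threshold: float  # POD 99th percentile
    flags: np.ndarray  # statistic (floored at 0) > threshold
    fst_hat: float  # fitted multi-locus null F
    pod_stats: np.ndarray = field(repr=False, default=None)
    contrast: str = ""


def pod_threshold(
    matrix: GenotypeMatrix,
    group1: np.ndarray,
    group2: np.ndarray,
    n_pod: int = 5000,
    quantile: float = 0.99,
    seed: int = 0,
    contrast: str = "",
) -> OutlierScan:
    """Empirical outlier threshold from pseudo-observed neutral data.

    Fits the neutral null from the data itself (multi-locus F_ST, observed
    minor-allele-frequency spectrum, observed group sample sizes), simulates
    ``n_pod`` neutral loci under Balding–Nichols drift, and takes the
    ``quantile`` (1% tail by default) of the simulated statistic as the
    significance threshold for the observed scan.
    """
    group1, group2 = np.asarray(group1), np.asarray(group2)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x504F44])
    observed = fst_per_locus(matrix, group1, group2)
    fhat = multilocus_fst(matrix, group1, group2)
    if not np.isfinite(fhat) or fhat <= 0:
        fhat = 1e-4
    both = np.concatenate([group1, group2])
    maf = matrix.maf(both)
    maf_pool = maf[np.isfinite(maf) & (maf > 0)]
    if len(maf_pool) == 0:
        raise ValueError("no polymorphic loci to resample the frequency spectrum from")
    p_anc = rng.choice(maf_pool, size=n_pod)
    n1, n2 = len(group1), len(group2)
    dosages = np.full((n_pod, n1 + n2), -1, dtype=np.int16)
    for cols, n in ((np.arange(n1), n1), (np.arange(n1, n1 + n2), n2)):
        alpha = p_anc * (1 - fhat) / fhat
        beta = (1 - p_anc) * (1 - fhat) / fhat
        p_pop = rng.beta(alpha, beta)
        dosages[:, cols] = rng.binomial(2, p_pop[:, None], size=(n_pod, n))
    pod = GenotypeMatrix(
        dosages,
        pd.DataFrame({"chrom": "pod", "pos": np.arange(n_pod) + 1, "type": "SNP",
                      "end": None, "length": 1, "id": [f"pod{i}" for i in range(n_pod)]}),
        pd.DataFrame({"sample": [f"s{i}" for i in range(n1 + n2)],
                      "population": ["g1"] * n1 + ["g2"] * n2,
                      "batch": "pod"}),
    )
    pod_theta = fst_per_locus(pod, np.arange(n1), np.arange(n1, n1 + n2))
    pod_stats = np.maximum(np.nan_to_num(pod_theta, nan=0.0), 0.0)
    threshold = float(np.quantile(pod_stats, quantile))
    flags = np.maximum(np.nan_to_num(observed, nan=0.0), 0.0) > threshold
    flags &= np.isfinite(observed)
    return OutlierScan(statistic=observed, threshold=threshold, flags=flags,
                       fst_hat=fhat, pod_stats=pod_stats, contrast=contrast)


# ---------------------------------------------------------------------------
# beta(1) balancing-selection scan
# ---------------------------------------------------------------------------

def _fold(k: np.ndarray, n: int) -> np.ndarray:
    return np.minimum(k, n - k) / n


def beta_kernel(f: np.ndarray, f_core: float, m_max: float, p: float = 2.0) -> np.ndarray:
    """Frequency-similarity kernel g(f, f_c) = (1 - |f - f_c| / M_c)^p."""
    return (1.0 - np.abs(f - f_core) / m_max) ** p


def _beta_normalizers(n: int, f_core: float, p: float = 2.0) -> tuple[float, float, float]:
    """(a_n, M_c, b_n): Watterson constant, kernel range, unbiasedness normalizer."""
    a_n = float(np.sum(1.0 / np.arange(1, n)))
    ks = np.arange(1, n // 2 + 1)
    folded = ks / n
    m_max = float(np.max(np.abs(folded - f_core)))
    c_nk = (1.0 / ks + 1.0 / (n - ks)) / (1.0 + (ks == n - ks))
    b_n = float(np.sum(beta_kernel(folded, f_core, m_max, p) * c_nk))
    return a_n, m_max, b_n


def beta_scan(
    matrix: GenotypeMatrix,
    population: str | list[str] | None = None,
    window: int = 1000,
    min_maf: float = 0.15,
    p: float = 2.0,
) -> pd.DataFrame:
    """Folded beta(1) score for every qualifying core SNP.

    The matrix is restricted to the focal population; sites fixed within it
    are excluded.  Cores need folded frequency >= ``min_maf`` (0.15: low-
    frequency cores mostly reflect drift and inflate false positives).  Every
    other polymorphic site within +-``window`` bp contributes its folded
    frequency through the similarity kernel.  Windows with no neighbours get
    beta = 0 with S = 0.  Requires >= 4 alleles.
    """
    m = matrix if population is None else matrix.take_samples(matrix.population_index(population))
    j, n_alleles = m.allele_counts()
    n = int(2 * m.n_samples)
    if n < 4:
        raise ValueError("need at least 4 alleles (2 diploid samples)")
    # effective folded count on the full-allele scale (missingness rescaled)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, j / np.maximum(n_alleles, 1), 0.0)
    folded = np.minimum(freq, 1 - freq)
    poly = (j > 0) & (j < n_alleles)
    chroms = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero((chroms == chrom) & poly)
        cpos = pos[cidx]
        order = np.argsort(cpos, kind="stable")
        cidx, cpos = cidx[order], cpos[order]
        cfold = folded[cidx]
        cores = np.flatnonzero(cfold >= min_maf)
        lo = np.searchsorted(cpos, cpos[cores] - window, side="left")
        hi = np.searchsorted(cpos, cpos[cores] + window, side="right")
        for c, l, h in zip(cores, lo, hi):
            f_c = float(cfold[c])
            neighbours = np.concatenate([cfold[l:c], cfold[c + 1:h]])
            S = int(len(neighbours))
            if S == 0:
                rows.append({"chrom": chrom, "pos": int(cpos[c]), "id": m.sites["id"].iloc[cidx[c]],
                             "f_core": f_c, "S": 0, "theta_beta": 0.0, "theta_w": 0.0,
                             "beta": 0.0})
                continue
            a_n, m_max, b_n = _beta_normalizers(n, f_c, p)
            theta_w = S / a_n
            theta_b = float(np.sum(beta_kernel(neighbours, f_c, m_max, p))) / b_n
            rows.append({"chrom": chrom, "pos": int(cpos[c]), "id": m.sites["id"].iloc[cidx[c]],
                         "f_core": f_c, "S": S, "theta_beta": theta_b, "theta_w": theta_w,
                         "beta": theta_b - theta_w})
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "f_core", "S",
                                       "theta_beta", "theta_w", "beta"])


# ---------------------------------------------------------------------------
# pseudo-beta(1) for SVs
# ---------------------------------------------------------------------------

def trimmed_mean(scores: np.ndarray, trim: float = 0.1) -> float:
    """Symmetric trimmed mean discarding floor(trim/2 * k) values per tail."""
    scores = np.sort(np.asarray(scores, dtype=float))
    k = len(scores)
    t = int(np.floor(trim / 2.0 * k))
    kept = scores[t:k - t] if t > 0 else scores
    return float(kept.mean())


def pseudo_beta(
    sv_records: list[VariantRecord],
    beta_scores: pd.DataFrame,
    mode: str = "per_sv_trimmed",
    window: int = 1000,
    trim: float = 0.1,
) -> pd.DataFrame:
    """SV-level balancing-selection score from upstream SNP beta(1) scores.

    Collects scores of SNPs with position in ``[breakend - window, breakend)``
    (half-open: a SNP exactly at the break end is excluded, one exactly
    ``window`` bp upstream is included).  ``per_sv_trimmed`` returns one
    trimmed-mean score per SV (NaN with k=0 when no SNP is upstream);
    ``pooled`` returns the raw collected scores, one row per (SV, SNP) pair.
    """
    if mode not in ("per_sv_trimmed", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom = {c: g.sort_values("pos") for c, g in beta_scores.groupby("chrom")}
    rows = []
    for rec in sv_records:
        g = by_chrom.get(rec.chrom)
        if g is None:
            scores = np.empty(0)
        else:
            gpos = g["pos"].to_numpy()
            l = np.searchsorted(gpos, rec.breakend - window, side="left")
            h = np.searchsorted(gpos, rec.breakend, side="left")
            scores = g["beta"].to_numpy()[l:h]
        if mode == "per_sv_trimmed":
            rows.append({
                "sv_id": rec.variant_id, "sv_type": rec.sv_type, "k": int(len(scores)),
                "pseudo_beta": trimmed_mean(scores, trim) if len(scores) else np.nan,
            })
        else:
            for s in scores:
                rows.append({"sv_id": rec.variant_id, "sv_type": rec.sv_type,
                             "k": int(len(scores)), "pseudo_beta": float(s)})
    return pd.DataFrame(rows, columns=["sv_id", "sv_type", "k", "pseudo_beta"])


# ---------------------------------------------------------------------------
# seven-group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    H: float
    df: int
    p_value: float
    group_summary: pd.DataFrame  # group, n, mean, se
    dunn: pd.DataFrame  # group_i, group_j, z, p, p_adjusted
    dropped: list[str]


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "fdr_bh") -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction."""
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = np.array([len(groups[g]) for g in names])
    N = len(values)
    ranks = scipy.stats.rankdata(values)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(names)}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for i in range(len(names)):
        for jj in range(i + 1, len(names)):
            gi, gj = names[i], names[jj]
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[jj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            p = 2.0 * scipy.stats.norm.sf(abs(z))
            rows.append({"group_i": gi, "group_j": gj, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p"], method=adjust)[1]
    return out


def group_comparison(groups: dict[str, np.ndarray], adjust: str = "fdr_bh") -> GroupComparison:
    """Kruskal-Wallis across score groups with Dunn's post hoc.

    Groups with fewer than two members are dropped (mirroring the removal of
    variant classes with a single observation); fewer than two surviving
    groups is an error.
    """
    clean = {g: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
             for g, v in groups.items()}
    dropped = [g for g, v in clean.items() if len(v) < 2]
    clean = {g: v for g, v in clean.items() if len(v) >= 2}
    if len(clean) < 2:
        raise ValueError("fewer than two groups with >= 2 members")
    values = list(clean.values())
    if all(np.all(v == values[0][0]) for v in values):  # all-tie degenerate case
        H, p = 0.0, 1.0
    else:
        H, p = scipy.stats.kruskal(*values)
    summary = pd.DataFrame([
        {"group": g, "n": len(v), "mean": float(v.mean()),
         "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan}
        for g, v in clean.items()
    ])
    return GroupComparison(H=float(H), df=len(clean) - 1, p_value=float(p),
                           group_summary=summary, dunn=dunn_test(clean, adjust),
                           dropped=dropped)


def seven_groups(
    beta_scores: pd.DataFrame,
    snp_outlier_ids: set[str],
    pseudo: pd.DataFrame,
    sv_outlier_ids: set[str],
) -> dict[str, np.ndarray]:
    """Assemble the seven score groups for the balancing-selection contrast.

    SNPs split into outlier / non-outlier; SVs into outliers (pooled over
    contrasts, not split by type) and per-type non-outliers (DEL, DUP, TRA,
    INV).  SVs without an upstream score (k=0) are excluded.
    """
    snp_out = beta_scores["id"].isin(snp_outlier_ids).to_numpy()
    groups: dict[str, np.ndarray] = {
        "outlier_SNP": beta_scores.loc[snp_out, "beta"].to_numpy(),
        "nonoutlier_SNP": beta_scores.loc[~snp_out, "beta"].to_numpy(),
    }
    scored = pseudo.dropna(subset=["pseudo_beta"])
    sv_out = scored["sv_id"].isin(sv_outlier_ids).to_numpy()
    groups["outlier_SV"] = scored.loc[sv_out, "pseudo_beta"].to_numpy()
    for t in ("DEL", "DUP", "TRA", "INV"):
        sel = (~sv_out) & (scored["sv_type"] == t).to_numpy()
        groups[f"nonoutlier_{t}"] = scored.loc[sel, "pseudo_beta"].to_numpy()
    return groups
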