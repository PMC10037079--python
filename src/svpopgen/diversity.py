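"""Per-population diversity, private alleles, folded SFS, and PCA.

All statistics run on the shared dosage matrix, so SNP and SV datasets are
analysed identically: an SV's alternate allele is carriage of the variant and
enters H_O / H_E / pi exactly as a SNP allele would.

Per-site definitions within a population with ``n`` non-missing alleles of
which ``j`` are the alternate:

* observed heterozygosity ``H_O`` — heterozygous genotypes / called genotypes;
* gene diversity ``H_E = 1 - p^2 - q^2`` from the sample frequency ``p=j/n``;
* nucleotide diversity ``pi = 2 j (n-j) / (n (n-1))``, the expected pairwise
  difference (unbiased; equals ``H_E * n/(n-1)``).

Population-level values are means over all retained sites (variant-site
averaging: the input is a variant-only callset, so only relative patterns
across populations are interpretable, not absolute per-bp diversity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from svpopgen.vcfio import GenotypeMatrix, VariantRecord, _interval_trees

SFS_CLASSES = ("no_overlap", "breakend_overlap", "complete_overlap")


def _per_pop_counts(matrix: GenotypeMatrix, pop_idx: np.ndarray):
    d = matrix.dosages[:, pop_idx]
    called = (d >= 0).sum(axis=1)
    j = np.where(d >= 0, d, 0).sum(axis=1)
    het = (d == 1).sum(axis=1)
    return j.astype(float), (2 * called).astype(float), het.astype(float), called.astype(float)


def diversity(matrix: GenotypeMatrix, subset: list[str] | None = None) -> pd.DataFrame:
    """Diversity table per population: H_O, H_E, pi, polymorphic and private counts.

    ``subset`` restricts the analysis to the named samples first (e.g. a
    single sequencing batch).  Private alleles are alleles (reference or
    alternate) observed in exactly one of the compared populations.
    """
    m = matrix if subset is None else matrix.take_samples(np.asarray(subset))
    pops = list(dict.fromkeys(m.samples["population"]))
    presence_ref = {}
    presence_alt = {}
    stats = {}
    for pop in pops:
        idx = m.population_index(pop)
        j, n, het, called = _per_pop_counts(m, idx)
        ok = n > 0  # sites with at least one called genotype in this population
        p = np.where(ok, j / np.maximum(n, 1), np.nan)
        h_o = np.where(ok, het / np.maximum(called, 1), np.nan)
        h_e = 1 - p**2 - (1 - p) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(n > 1, 2 * j * (n - j) / (n * np.maximum(n - 1, 1)), np.nan)
        poly = ok & (j > 0) & (j < n)
        presence_ref[pop] = ok & (j < n)
        presence_alt[pop] = ok & (j > 0)
        stats[pop] = {
            "population": pop, "n_samples": int(len(idx)),
            "H_O": float(np.nanmean(h_o)), "H_E": float(np.nanmean(np.where(ok, h_e, np.nan))),
            "pi": float(np.nanmean(pi)), "n_polymorphic": int(poly.sum()),
        }
    for pop in pops:
        others_ref = np.any([presence_ref[q] for q in pops if q != pop], axis=0)
        others_alt = np.any([presence_alt[q] for q in pops if q != pop], axis=0)
        private = (presence_ref[pop] & ~others_ref).sum() + (presence_alt[pop] & ~others_alt).sum()
        stats[pop]["private_alleles"] = int(private)
    return pd.DataFrame([stats[p] for p in pops])


def invader_specific(
    matrix: GenotypeMatrix,
    invader_pops: list[str],
    excluded_samples: list[str] | None = None,
) -> list[str]:
    """Variant ids whose alternate allele occurs only in the invader populations.

    Excluded samples (e.g. an admixed range-edge deme) are dropped before
    counting; reference populations are all remaining non-invader populations.
    """
    m = matrix
    if excluded_samples:
        keep = ~m.samples["sample"].isin(excluded_samples).to_numpy()
        m = m.take_samples(keep)
    inv_idx = m.population_index(invader_pops)
    ref_idx = np.setdiff1d(np.arange(m.n_samples), inv_idx)
    j_inv, _, _, _ = _per_pop_counts(m, inv_idx)
    j_ref, _, _, _ = _per_pop_counts(m, ref_idx)
    mask = (j_inv > 0) & (j_ref == 0)
    return list(m.sites.loc[mask, "id"])


def common_filter(variant_ids: list[str], matrix: GenotypeMatrix,
                  min_maf: float = 0.15,
                  sample_idx: np.ndarray | None = None) -> list[str]:
    """Retain variants with MAF strictly above ``min_maf`` (0.15 default)."""
    maf = matrix.maf(sample_idx)
    by_id = dict(zip(matrix.sites["id"], maf))
    return [v for v in variant_ids if np.nan_to_num(by_id.get(v, 0.0)) > min_maf]


def classify_gene_overlap(records: list[VariantRecord], genes: pd.DataFrame) -> list[str]:
    """Assign each SV to an SFS class by its relationship to gene spans.

    ``complete_overlap`` — the SV interval contains at least one whole gene;
    ``breakend_overlap`` — at least one break end lies inside a gene (and not
    complete); ``no_overlap`` otherwise.
    """
    trees = _interval_trees(genes)
    out = []
    for rec in records:
        s, e = rec.interval0()
        tree = trees.get(rec.chrom)
        cls = "no_overlap"
        if tree is not None:
            hits = [h for h in tree.overlap(s, e) if h.begin < e and h.end > s]
            if any(h.begin >= s and h.end <= e for h in hits):
                cls = "complete_overlap"
            else:
                # any remaining overlap necessarily involves a break end
                # (gene contained => complete; otherwise an SV edge is inside)
                if hits:
                    cls = "breakend_overlap"
        out.append(cls)
    return out


def folded_sfs(matrix: GenotypeMatrix, class_labels: list[str] | None = None,
               bin_width: float = 0.05) -> pd.DataFrame:
    """Folded site-frequency histogram, optionally split by gene-overlap class.

    Fixed bins of width 0.05 over (0, 0.5]; a folded frequency of exactly 0.5
    falls in the top bin.  Monomorphic sites land in the lowest bin so each
    class histogram sums to the class size.
    """
    maf = np.nan_to_num(matrix.maf(), nan=0.0)
    n_bins = int(round(0.5 / bin_width))
    bins = np.clip(np.ceil(maf / bin_width).astype(int) - 1, 0, n_bins - 1)
    labels = class_labels if class_labels is not None else ["all"] * matrix.n_sites
    rows = []
    for cls in dict.fromkeys(labels):
        idx = np.array([l == cls for l in labels])
        hist = np.bincount(bins[idx], minlength=n_bins)
        for b in range(n_bins):
            rows.append({"class": cls, "bin_low": b * bin_width,
                         "bin_high": (b + 1) * bin_width, "count": int(hist[b])})
    return pd.DataFrame(rows)


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x PCs
    explained_variance: np.ndarray  # fractions
    n_sites_used: int


def pca(matrix: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the dosage matrix with allele-frequency standardization.

    Missing dosages are mean-imputed; each site is centred by ``2 p`` and
    scaled by ``sqrt(2 p (1-p))`` where ``p`` is the sample allele frequency
    (zero-variance sites dropped).  Sign convention: the largest-magnitude
    site loading of each component is positive, so coordinates reproduce.
    """
    if matrix.n_samples < 2 or matrix.n_sites < 2:
        raise ValueError("need at least 2 samples and 2 sites")
    d = matrix.dosages.astype(float).T  # samples x sites
    miss = d < 0
    j, n = matrix.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, j / np.maximum(n, 1), np.nan)
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("all sites are monomorphic or uncalled")
    d, p = d[:, keep], p[keep]
    mu = 2 * p
    d = np.where(miss[:, keep], mu, d)
    X = (d - mu) / np.sqrt(2 * p * (1 - p))
    n_comp = min(n_components, matrix.n_samples - 1, X.shape[1])
    U, S, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    ev = S**2
    for k in range(n_comp):
        i = np.argmax(np.abs(Vt[k]))
        if Vt[k, i] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U[:, :n_comp] * S[:n_comp]
    table = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(n_comp)])
    table.insert(0, "sample", matrix.sample_ids())
    table.insert(1, "population", list(matrix.samples["population"]))
    return PcaResult(table, ev[:n_comp] / ev.sum(), int(keep.sum()))
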