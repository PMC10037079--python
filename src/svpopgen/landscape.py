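"""Genomic-landscape comparison of SNP and SV distributions.

Counts both variant classes in fixed 1-Mb windows, regresses SV counts on
SNP counts with a quasipoisson GLM, and asks where SVs are over- or
under-represented relative to what local SNP density predicts — in
particular near chromosome ends, where subtelomeric repeat structure is
expected to concentrate structural variation.  Also provides gene-overlap
breakdowns by variant size class, classification of SV break ends against a
repeat annotation (30-bp rule), and per-individual heterozygosity summaries
used as a batch-effect screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from svpopgen.vcfio import GenotypeMatrix, VariantRecord, _interval_trees

SIZE_CLASSES = ("1 bp", "30-99 bp", "100-999 bp", "1-10 kb", ">=10 kb")


def bin_counts(
    snp_sites: pd.DataFrame,
    sv_records: list[VariantRecord],
    chrom_lengths: dict[str, int],
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """SNP and SV counts per fixed window.

    Windows tile each chromosome from 0; the last window is truncated.  SNPs
    are counted at their position; SVs are counted in *every* window their
    interval overlaps (coverage semantics), so the summed SV column can
    exceed the number of SV records.  TRA and INS occupy their break-end /
    insertion point only.
    """
    snp_by_chrom = {c: g["pos"].to_numpy() for c, g in snp_sites.groupby("chrom")}
    rows = []
    sv_index: dict[str, tuple[int, np.ndarray]] = {}
    for chrom, L in chrom_lengths.items():
        n_bins = max(1, int(np.ceil(L / bin_size)))
        pos = snp_by_chrom.get(chrom, np.empty(0, dtype=int))
        snp_counts = np.bincount(
            np.clip((pos.astype(int) - 1) // bin_size, 0, n_bins - 1), minlength=n_bins
        ) if len(pos) else np.zeros(n_bins, dtype=int)
        sv_counts = np.zeros(n_bins, dtype=int)
        sv_index[chrom] = (n_bins, sv_counts)
        for b in range(n_bins):
            rows.append({"chrom": chrom, "start": b * bin_size,
                         "end": min((b + 1) * bin_size, L), "snp_count": int(snp_counts[b])})
    for rec in sv_records:
        if rec.chrom not in sv_index:
            continue
        n_bins, sv_counts = sv_index[rec.chrom]
        s, e = rec.interval0()
        for b in range(s // bin_size, min(max(e - 1, s) // bin_size, n_bins - 1) + 1):
            sv_counts[b] += 1
    windows = pd.DataFrame(rows)
    windows["sv_count"] = np.concatenate([sv_index[c][1] for c in chrom_lengths])
    return windows[["chrom", "start", "end", "snp_count", "sv_count"]]


@dataclass
class DensityRegression:
    slope: float
    intercept: float
    t_value: float
    dispersion: float
    fitted: np.ndarray
    residuals: np.ndarray  # deviance residuals
    degenerate: bool = False


def density_regression(windows: pd.DataFrame, residual_type: str = "deviance") -> DensityRegression:
    """Quasipoisson regression of SV count on SNP count per window.

    Point estimates are the Poisson IRLS fit; the dispersion is estimated by
    Pearson chi^2 / df and inflates the standard errors, so the reported
    t-value is coefficient / quasi-SE.  Residuals are deviance residuals by
    default (``residual_type='pearson'`` for the alternative).
    """
    if len(windows) < 10:
        raise ValueError("need at least 10 windows")
    y = windows["sv_count"].to_numpy(dtype=float)
    x = windows["snp_count"].to_numpy(dtype=float)
    if np.all(y == 0):
        return DensityRegression(np.nan, np.nan, np.nan, np.nan,
                                 np.zeros_like(y), np.zeros_like(y), degenerate=True)
    X = np.column_stack([np.ones_like(x), x])
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
    resid = fit.resid_deviance if residual_type == "deviance" else fit.resid_pearson
    with np.errstate(invalid="ignore", divide="ignore"):
        t = float(fit.params[1] / fit.bse[1]) if fit.bse[1] > 0 else float("nan")
    return DensityRegression(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        t_value=t, dispersion=float(fit.scale),
        fitted=np.asarray(fit.fittedvalues), residuals=np.asarray(resid),
    )


def window_is_subtelomeric(windows: pd.DataFrame, chrom_lengths: dict[str, int],
                           subtelomere_frac: float) -> np.ndarray:
    """A window is subtelomeric if it overlaps either terminal window."""
    flags = np.zeros(len(windows), dtype=bool)
    for i, r in enumerate(windows.itertuples()):
        L = chrom_lengths[r.chrom]
        w = subtelomere_frac * L
        flags[i] = (r.start < w) or (r.end > L - w)
    return flags


def subtelomere_enrichment(windows: pd.DataFrame, residuals: np.ndarray,
                           chrom_lengths: dict[str, int],
                           subtelomere_frac: float) -> dict | None:
    """Mean SV-density residual in subtelomeric vs interior windows.

    Returns None when either class has fewer than two windows.  A positive
    ``difference`` with a small rank-sum p indicates SV enrichment near
    chromosome ends beyond what SNP density predicts.
    """
    sub = window_is_subtelomeric(windows, chrom_lengths, subtelomere_frac)
    r_sub, r_int = residuals[sub], residuals[~sub]
    if len(r_sub) < 2 or len(r_int) < 2:
        return None
    stat, p = scipy.stats.mannwhitneyu(r_sub, r_int, alternative="two-sided")
    return {
        "n_subtelomeric": int(len(r_sub)), "n_interior": int(len(r_int)),
        "mean_subtelomeric": float(r_sub.mean()), "mean_interior": float(r_int.mean()),
        "difference": float(r_sub.mean() - r_int.mean()),
        "rank_sum_U": float(stat), "p_value": float(p),
    }


def _size_class(rec: VariantRecord) -> str | None:
    if rec.sv_type == "SNP":
        return SIZE_CLASSES[0]
    if rec.length is None:  # TRA break ends have undefined size
        return None
    if rec.length < 100:
        return SIZE_CLASSES[1]
    if rec.length < 1000:
        return SIZE_CLASSES[2]
    if rec.length < 10_000:
        return SIZE_CLASSES[3]
    return SIZE_CLASSES[4]


def overlap_by_size_class(records: list[VariantRecord], genes: pd.DataFrame) -> pd.DataFrame:
    """Proportion of each variant size class overlapping 0 / 1 / >=2 gene spans.

    Records without a defined length (TRA break ends) are excluded, matching
    the convention of not assigning sizes to break-end calls.  Empty classes
    are omitted.
    """
    trees = _interval_trees(genes)
    counts: dict[str, list[int]] = {c: [0, 0, 0] for c in SIZE_CLASSES}
    for rec in records:
        cls = _size_class(rec)
        if cls is None:
            continue
        s, e = rec.interval0()
        tree = trees.get(rec.chrom)
        n = 0
        if tree is not None:
            n = sum(1 for h in tree.overlap(s, e) if h.begin < e and h.end > s)
        counts[cls][min(n, 2)] += 1
    rows = []
    for cls in SIZE_CLASSES:
        total = sum(counts[cls])
        if total == 0:
            continue
        rows.append({
            "size_class": cls, "n": total,
            "prop_0_genes": counts[cls][0] / total,
            "prop_1_gene": counts[cls][1] / total,
            "prop_2plus_genes": counts[cls][2] / total,
        })
    return pd.DataFrame(rows)


def classify_breakends(sv_records: list[VariantRecord], repeats: pd.DataFrame,
                       chrom_lengths: dict[str, int], window: int = 30) -> pd.DataFrame:
    """Classify each SV by the repeat content of its first 30 bp.

    The window starts at the first break end (truncated at the chromosome
    end); if any base overlaps a repeat interval the SV takes the class of
    the interval with the largest overlap, else "none".
    """
    trees = _interval_trees(repeats)
    rows = []
    for rec in sv_records:
        s = rec.pos - 1
        e = min(s + window, chrom_lengths.get(rec.chrom, s + window))
        tree = trees.get(rec.chrom)
        best_class, best_ov = "none", 0
        if tree is not None:
            for h in sorted(tree.overlap(s, e), key=lambda h: (h.begin, h.end, str(h.data))):
                ov = min(e, h.end) - max(s, h.begin)
                if ov > best_ov:
                    best_ov, best_class = ov, str(h.data)
        rows.append({"sv_id": rec.variant_id, "repeat_class": best_class,
                     "overlap_bp": best_ov})
    return pd.DataFrame(rows, columns=["sv_id", "repeat_class", "overlap_bp"])


def repeat_fraction(breakend_classes: pd.DataFrame) -> float:
    """Fraction of SVs whose break-end window touches any repeat."""
    if len(breakend_classes) == 0:
        return float("nan")
    return float((breakend_classes["repeat_class"] != "none").mean())


def individual_heterozygosity(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, dict]:
    """Per-sample heterozygous-site proportion plus a batch-effect rank test.

    Returns (per-sample table, Kruskal-Wallis summary across batch labels).
    Samples with no called sites get NaN and are dropped from the test.
    """
    d = matrix.dosages
    called = (d >= 0).sum(axis=0)
    het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        prop = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    table = matrix.samples.copy()
    table["n_called"] = called
    table["het_proportion"] = prop
    groups = [g["het_proportion"].dropna().to_numpy()
              for _, g in table.groupby("batch") if g["het_proportion"].notna().any()]
    if len(groups) >= 2 and all(len(g) > 0 for g in groups):
        try:
            H, p = scipy.stats.kruskal(*groups)
        except ValueError:  # all values identical
            H, p = 0.0, 1.0
        test = {"H": float(H), "df": len(groups) - 1, "p_value": float(p)}
    else:
        test = {"H": np.nan, "df": 0, "p_value": np.nan}
    return table, test
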