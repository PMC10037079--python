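"""Dataset-construction filters: missingness/MAF, LD pruning, thinning, kinship.

These reproduce the standard vcftools/bcftools-style filter chain used to
build population-genetic datasets: sites are dropped for excess missingness
or low minor allele frequency, pruned for linkage by pairwise genotype r^2
within a base-pair window, physically thinned to independence, and the
sample set screened for cryptic relatives with the KING-robust kinship
estimator.  Every operation is idempotent and reports exact removal counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from svpopgen.vcfio import GenotypeMatrix


@dataclass(frozen=True)
class FilterParams:
    max_missing: float = 0.5  # max fraction of missing genotypes per site
    min_maf: float = 0.03  # retain sites with MAF >= this (tool convention)
    ld_r2_max: float = 0.6
    ld_window: int = 1000  # pairwise distance in bp
    thin_distance: int = 5000  # keep sites > this far apart
    common_maf: float = 0.15  # strict > for the "common variant" filter
    kinship_flag: float = 0.25

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_maf", "common_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.ld_r2_max <= 1.0:
            raise ValueError("ld_r2_max outside [0, 1]")
        if self.ld_window <= 0 or self.thin_distance <= 0:
            raise ValueError("windows must be positive")


def filter_missing_maf(matrix: GenotypeMatrix, params: FilterParams | None = None) -> GenotypeMatrix:
    """Drop sites with missingness above ``max_missing`` or MAF below ``min_maf``.

    MAF is computed on non-missing alleles; all-missing and monomorphic sites
    are removed (MAF 0 < any positive threshold).
    """
    params = params or FilterParams()
    miss = matrix.missing_fraction()
    maf = matrix.maf()
    keep = (miss <= params.max_missing) & (np.nan_to_num(maf, nan=-1.0) >= params.min_maf)
    return matrix.take_sites(keep)


def _r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing samples."""
    mask = (d1 >= 0) & (d2 >= 0)
    if mask.sum() < 2:
        return 0.0
    x = d1[mask].astype(float)
    y = d2[mask].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / np.sqrt(vx * vy)
    return float(r * r)


def ld_prune(matrix: GenotypeMatrix, params: FilterParams | None = None) -> GenotypeMatrix:
    """Sequential LD pruning: first-retained-wins within each chromosome.

    Scanning sites in position order, a site is removed if its genotype r^2
    with any previously retained site within ``ld_window`` bp exceeds
    ``ld_r2_max``.  Zero-variance pairs have undefined r^2, treated as 0.
    Chromosomes are independent, so processing order cannot change the result.
    """
    params = params or FilterParams()
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    keep = np.zeros(matrix.n_sites, dtype=bool)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        kept: list[int] = []
        for i in idx:
            drop = False
            for j in reversed(kept):
                if pos[i] - pos[j] > params.ld_window:
                    break
                if _r2(matrix.dosages[i], matrix.dosages[j]) > params.ld_r2_max:
                    drop = True
                    break
            if not drop:
                kept.append(i)
                keep[i] = True
    return matrix.take_sites(keep)


def thin(matrix: GenotypeMatrix, thin_distance: int = 5000) -> GenotypeMatrix:
    """Greedy physical thinning: keep a site iff it is more than
    ``thin_distance`` bp after the last kept site on its chromosome."""
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    keep = np.zeros(matrix.n_sites, dtype=bool)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        last = None
        for i in idx:
            if last is None or pos[i] - last > thin_distance:
                keep[i] = True
                last = pos[i]
    return matrix.take_sites(keep)


def kinship_king(matrix: GenotypeMatrix) -> pd.DataFrame:
    """KING-robust pairwise kinship over jointly non-missing sites.

    phi = (N_het,het - 2 N_opposite_hom) / (N_het,i + N_het,j); a duplicated
    sample gives 0.5, parent-offspring ~0.25, unrelated ~0.  Undefined
    denominators yield NaN.
    """
    d = matrix.dosages
    ids = matrix.sample_ids()
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = d[:, i], d[:, j]
        mask = (a >= 0) & (b >= 0)
        ai, bj = a[mask], b[mask]
        het_i = int((ai == 1).sum())
        het_j = int((bj == 1).sum())
        het_het = int(((ai == 1) & (bj == 1)).sum())
        opp = int((((ai == 0) & (bj == 2)) | ((ai == 2) & (bj == 0))).sum())
        denom = het_i + het_j
        phi = (het_het - 2 * opp) / denom if denom > 0 else np.nan
        rows.append({"sample_i": ids[i], "sample_j": ids[j], "kinship": phi})
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "kinship"])


def relatedness_check(matrix: GenotypeMatrix, flag_at: float = 0.25) -> pd.DataFrame:
    """Kinship table with a ``flagged`` column for pairs at or above ``flag_at``."""
    table = kinship_king(matrix)
    table["flagged"] = table["kinship"] >= flag_at
    return table


def apply_filters(matrix: GenotypeMatrix, params: FilterParams | None = None,
                  do_ld: bool = True, do_thin: bool = True) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Run the filter chain and return (matrix, per-stage ledger).

    The ledger accounts exactly: sites_in = sites_out + removed per stage.
    Read-depth filters used on real callsets are not applicable here (no
    depths are simulated) and are logged as skipped.
    """
    params = params or FilterParams()
    stages: list[dict] = []
    m = matrix
    n0 = m.n_sites
    m = filter_missing_maf(m, params)
    stages.append({"stage": "missing_maf", "sites_in": n0, "sites_out": m.n_sites,
                   "removed": n0 - m.n_sites})
    if do_ld:
        n0 = m.n_sites
        m = ld_prune(m, params)
        stages.append({"stage": "ld_prune", "sites_in": n0, "sites_out": m.n_sites,
                       "removed": n0 - m.n_sites})
    if do_thin:
        n0 = m.n_sites
        m = thin(m, params.thin_distance)
        stages.append({"stage": "thin", "sites_in": n0, "sites_out": m.n_sites,
                       "removed": n0 - m.n_sites})
    stages.append({"stage": "mean_depth (skipped: no depths)", "sites_in": m.n_sites,
                   "sites_out": m.n_sites, "removed": 0})
    return m, pd.DataFrame(stages)
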