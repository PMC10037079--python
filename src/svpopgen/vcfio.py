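"""Variant I/O and the shared genotype matrix.

All downstream statistics (diversity, F_ST, beta scans) run on the same
dosage representation for SNPs and SVs alike: structural variants are treated
as biallelic loci whose alternate allele is carriage of the variant, so a
sites-by-samples matrix of 0/1/2/missing covers both variant classes.

Coordinate conventions: VCF positions are 1-based with inclusive END; all
internal interval arithmetic is 0-based half-open, converted only at I/O
boundaries.  TRA records are single break ends and occupy a 1-bp interval;
INS likewise occupy their insertion point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "INS", "TRA")
MISSING = -1

#: genotype string for each dosage value
_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


@dataclass
class VariantRecord:
    """One biallelic variant (SNP or SV) with per-sample dosages.

    ``pos`` is 1-based (VCF convention); ``end`` is the 1-based inclusive end
    coordinate and is absent for SNP, INS and TRA; ``length`` is absent for
    TRA (break ends have no defined size).  ``genotypes`` maps sample id to
    alternate-allele dosage (0/1/2, or -1 for missing).
    """

    chrom: str
    pos: int
    sv_type: str
    genotypes: dict[str, int]
    end: int | None = None
    length: int | None = None
    strands: str | None = None
    filter: str = "PASS"
    caller: str | None = None
    variant_id: str | None = None
    ref: str = "N"
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES and self.sv_type != "SNP":
            raise ValueError(f"unknown variant type {self.sv_type!r}")
        if self.end is not None and self.end < self.pos:
            raise ValueError(
                f"record {self.chrom}:{self.pos} ({self.sv_type}): END "
                f"{self.end} < POS {self.pos}"
            )

    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval used for all overlap logic."""
        if self.sv_type in ("SNP", "INS", "TRA") or self.end is None:
            return self.pos - 1, self.pos
        return self.pos - 1, self.end

    @property
    def breakend(self) -> int:
        """1-based coordinate of the first (left) break end."""
        return self.pos


@dataclass
class GenotypeMatrix:
    """Sites x samples alternate-allele dosage matrix shared by SNP and SV analyses.

    ``dosages`` holds 0/1/2 with -1 for missing.  ``sites`` carries
    (chrom, pos, type, end, length, id) in (chrom, pos) order; ``samples``
    carries (sample, population, batch).
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage shape does not match site/sample tables")

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def sample_ids(self) -> list[str]:
        return list(self.samples["sample"])

    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, non-missing allele count)."""
        d = self.dosages if sample_idx is None else self.dosages[:, sample_idx]
        called = d >= 0
        j = np.where(called, d, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
        return j.astype(np.int64), n.astype(np.int64)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Minor allele frequency among non-missing alleles (NaN if no calls)."""
        j, n = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, j / np.maximum(n, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.dosages < 0).mean(axis=1)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[idx],
            self.sites.iloc[idx].reset_index(drop=True),
            self.samples,
        )

    def take_samples(self, which) -> "GenotypeMatrix":
        """Subset samples by boolean mask, integer index, or sample ids."""
        which = np.asarray(which)
        if which.dtype == bool:
            idx = np.flatnonzero(which)
        elif which.dtype.kind in "iu":
            idx = which
        else:
            order = {s: i for i, s in enumerate(self.samples["sample"])}
            idx = np.array([order[s] for s in which])
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.sites,
            self.samples.iloc[idx].reset_index(drop=True),
        )

    def population_index(self, population: str | list[str]) -> np.ndarray:
        pops = [population] if isinstance(population, str) else list(population)
        return np.flatnonzero(self.samples["population"].isin(pops).to_numpy())


def _dosage_from_pair(a: int, b: int) -> int:
    if a < 0 or b < 0:
        return MISSING
    return int(a > 0) + int(b > 0)


def read_vcf(path: str, pass_only: bool = False) -> list[VariantRecord]:
    """Read biallelic SNP/SV records from a VCF.

    With ``pass_only``, records whose FILTER is not PASS are dropped.
    Multi-allelic records and symbolic-allele records lacking SVTYPE are
    rejected with a logged warning.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    n_rejected = 0
    for v in vcf:
        if len(v.ALT) != 1:
            logger.warning("rejecting multi-allelic record %s:%d", v.CHROM, v.POS)
            n_rejected += 1
            continue
        alt = v.ALT[0]
        svtype = v.INFO.get("SVTYPE")
        symbolic = alt.startswith("<") or alt in ("]", "[") or "[" in alt or "]" in alt
        if svtype is None:
            if symbolic:
                logger.warning(
                    "rejecting symbolic record without SVTYPE %s:%d", v.CHROM, v.POS
                )
                n_rejected += 1
                continue
            svtype = "SNP" if len(v.REF) == 1 and len(alt) == 1 else None
            if svtype is None:
                logger.warning("rejecting non-SNP sequence record %s:%d", v.CHROM, v.POS)
                n_rejected += 1
                continue
        filt = v.FILTER or "PASS"  # cyvcf2 reports PASS as None
        if pass_only and filt != "PASS":
            continue
        end = v.INFO.get("END") if svtype in ("DEL", "DUP", "INV") else None
        svlen = v.INFO.get("SVLEN")
        if svlen is not None:
            svlen = abs(int(svlen))
        elif svtype == "SNP":
            svlen = 1
        gts = {
            s: _dosage_from_pair(g[0], g[1]) for s, g in zip(samples, v.genotypes)
        }
        rec = VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            sv_type=svtype,
            genotypes=gts,
            end=int(end) if end is not None else None,
            length=svlen,
            strands=v.INFO.get("STRANDS"),
            filter=filt,
            variant_id=v.ID,
            ref=v.REF,
            alt=alt,
        )
        out.append(rec)
    if n_rejected:
        logger.warning("%d records rejected while reading %s", n_rejected, path)
    return out


def write_vcf(
    records: list[VariantRecord],
    path: str,
    samples: list[str] | None = None,
    contigs: dict[str, int] | None = None,
    extra_info: dict[str, dict] | None = None,
) -> None:
    """Write records as VCF v4.2 with SVTYPE/END/SVLEN INFO and GT FORMAT.

    ``extra_info`` maps variant_id to additional INFO key/value pairs (used by
    the merge stage for SUPP / caller-id tags).
    """
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                seen.setdefault(s, None)
        samples = list(seen)
    lines = ["##fileformat=VCFv4.2"]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=STRANDS,Number=1,Type=String,Description="Break-end strand pair">',
        '##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Supporting caller count">',
        '##INFO=<ID=CALLERS,Number=1,Type=String,Description="Supporting caller ids">',
        '##FILTER=<ID=LowQual,Description="Failed caller filter">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for i, r in enumerate(sorted(records, key=lambda r: (r.chrom, r.pos))):
        if r.sv_type == "SNP":
            ref, alt = r.ref, r.alt or "T"
            info_parts = []
        else:
            ref, alt = r.ref, r.alt or f"<{r.sv_type}>"
            info_parts = [f"SVTYPE={r.sv_type}"]
            if r.end is not None:
                info_parts.append(f"END={r.end}")
            if r.length is not None:
                info_parts.append(f"SVLEN={r.length}")
            if r.strands is not None:
                info_parts.append(f"STRANDS={r.strands}")
        vid = r.variant_id or f"var{i}"
        if extra_info and vid in extra_info:
            info_parts += [f"{k}={v}" for k, v in extra_info[vid].items()]
        info = ";".join(info_parts) if info_parts else "."
        gts = "\t".join(_GT_STR[r.genotypes.get(s, MISSING)] for s in samples)
        lines.append(
            f"{r.chrom}\t{r.pos}\t{vid}\t{ref}\t{alt}\t.\t{r.filter}\t{info}\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_population_map(path: str) -> pd.DataFrame:
    """TSV of (sample, population, batch); header optional."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if "sample" not in cols:  # headerless file
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population", "batch"])
    else:
        df.columns = cols
    return df[["sample", "population", "batch"]]


def build_matrix(records: list[VariantRecord], population_map: pd.DataFrame) -> GenotypeMatrix:
    """Assemble the dosage matrix, sites sorted by (chrom, pos).

    Every sample appearing in the records must be present in the population
    map; unmapped samples raise ``ValueError``.
    """
    mapped = set(population_map["sample"])
    vcf_samples: dict[str, None] = {}
    for r in records:
        for s in r.genotypes:
            vcf_samples.setdefault(s, None)
    unmapped = [s for s in vcf_samples if s not in mapped]
    if unmapped:
        raise ValueError(f"samples missing from population map: {unmapped}")
    samples = population_map[population_map["sample"].isin(vcf_samples)].reset_index(drop=True)
    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    sample_list = list(samples["sample"])
    dos = np.full((len(records), len(sample_list)), MISSING, dtype=np.int16)
    rows = []
    for out_i, i in enumerate(order):
        r = records[i]
        for k, s in enumerate(sample_list):
            dos[out_i, k] = r.genotypes.get(s, MISSING)
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "type": r.sv_type,
                "end": r.end,
                "length": r.length,
                "id": r.variant_id or f"var{i}",
            }
        )
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "type", "end", "length", "id"])
    return GenotypeMatrix(dos, sites, samples)


def read_genes_gff3(path: str) -> pd.DataFrame:
    """Gene spans from a GFF3 as (chrom, start, end, gene_id), 0-based half-open."""
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    genes = df[df["Feature"] == "gene"]
    out = pd.DataFrame(
        {
            "chrom": genes["Chromosome"].astype(str),
            "start": genes["Start"].astype(int),
            "end": genes["End"].astype(int),
            "feature_id": genes["ID"].astype(str) if "ID" in genes else genes.index.astype(str),
        }
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def read_repeats_bed(path: str) -> pd.DataFrame:
    """Repeat intervals from BED (0-based half-open) with a class label column."""
    import pyranges as pr

    df = pr.read_bed(str(path)).df
    out = pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "feature_id": df["Name"].astype(str) if "Name" in df else "repeat",
        }
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _interval_trees(annotation: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annotation.groupby("chrom"):
        t = IntervalTree()
        for start, end, fid in zip(sub["start"], sub["end"], sub["feature_id"]):
            if end > start:
                t[start:end] = fid
        trees[str(chrom)] = t
    return trees


def intersect_annotation(
    records: list[VariantRecord],
    annotation: pd.DataFrame,
    mode: str = "any_overlap",
) -> list[list[str]]:
    """Per-record overlapping (or within-1-kb) annotation features.

    ``mode='within_1kb'`` reports features whose nearest edge lies at most
    1,000 bp (inclusive) from the record's interval.
    """
    if mode not in ("any_overlap", "within_1kb"):
        raise ValueError(f"unknown mode {mode!r}")
    pad = 1000 if mode == "within_1kb" else 0
    trees = _interval_trees(annotation)
    out: list[list[str]] = []
    for r in records:
        s, e = r.interval0()
        tree = trees.get(r.chrom)
        if tree is None:
            out.append([])
            continue
        hits = tree.overlap(s - pad - 1, e + pad + 1)
        feats = []
        for h in hits:
            if pad == 0:
                if h.begin < e and h.end > s:
                    feats.append(h.data)
            else:
                gap = max(0, h.begin - e, s - h.end)
                if gap <= pad:
                    feats.append(h.data)
        out.append(sorted(feats))
    return out
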