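"""End-to-end pipeline: simulate -> call -> merge -> filter -> analyse.

Mirrors the dataset ledger of a two-variant-class population-genomics study:

* ``unfiltered_sv`` — cohort SVs from the genotype-aware two-stage consensus
  merge of three callers (PASS calls only);
* ``popgen_sv`` — the unfiltered set after missingness/MAF filtering;
* ``wgs_snp`` — SNPs after missingness/MAF filtering and LD pruning (the
  high-density set used for balancing-selection scans);
* ``thinned_snp`` — the LD-pruned set physically thinned to independence
  (used for diversity, PCA and outlier scans).

Every stage records exact variant counts in the manifest; re-running with the
same configuration and seed reproduces all outputs byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from svpopgen import diversity as divmod_
from svpopgen import filters as filt
from svpopgen import landscape as land
from svpopgen import selection as sel
from svpopgen.merge import MergeParams, merge_across_samples, merge_per_sample
from svpopgen.simulate import SimConfig, Simulation
from svpopgen.vcfio import GenotypeMatrix, build_matrix, write_vcf

logger = logging.getLogger(__name__)

STAGES = ("simulate", "merge", "filter", "landscape", "diversity", "selection")


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    merge_params: MergeParams = field(default_factory=MergeParams)
    filter_params: filt.FilterParams = field(default_factory=filt.FilterParams)
    stages: tuple[str, ...] = STAGES
    native_pop: str = "UK"
    invader_subgroups: tuple[str, ...] = ("AU_EAST", "AU_SOUTH")
    invader_pops: tuple[str, ...] = ("AU_EAST", "AU_SOUTH")
    excluded_pops: tuple[str, ...] = ("MUNG",)  # admixed/extreme-drift demes
    bin_size: int = 100_000  # desk-scale analogue of 1-Mb windows on a Gb genome
    beta_window: int = 1000
    beta_min_maf: float = 0.15
    n_pod: int = 5000
    pod_quantile: float = 0.99

    def validate(self) -> list[str]:
        """Validate all parameter blocks; returns human-readable notes."""
        notes = []
        self.sim.validate()
        pops = {p.name for p in self.sim.populations}
        for name in (self.native_pop, *self.invader_subgroups, *self.invader_pops,
                     *self.excluded_pops):
            if name not in pops:
                raise ValueError(f"population {name!r} not in simulated cohort {sorted(pops)}")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if self.merge_params.min_len != 30:
            notes.append(f"min_len={self.merge_params.min_len} overrides the conventional 30 bp")
        return notes


@dataclass
class PipelineResult:
    manifest: dict
    truth: object = None
    genome: object = None
    unfiltered_sv: GenotypeMatrix | None = None
    popgen_sv: GenotypeMatrix | None = None
    wgs_snp: GenotypeMatrix | None = None
    thinned_snp: GenotypeMatrix | None = None
    cohort_svs: list | None = None
    windows: pd.DataFrame | None = None
    regression: land.DensityRegression | None = None
    enrichment: dict | None = None
    size_class_table: pd.DataFrame | None = None
    breakend_classes: pd.DataFrame | None = None
    het_table: pd.DataFrame | None = None
    het_test: dict | None = None
    diversity_snp: pd.DataFrame | None = None
    diversity_sv: pd.DataFrame | None = None
    pca_snp: divmod_.PcaResult | None = None
    pca_sv: divmod_.PcaResult | None = None
    invader_specific_ids: list[str] | None = None
    common_invader_ids: list[str] | None = None
    sfs: pd.DataFrame | None = None
    snp_scans: list[sel.OutlierScan] | None = None
    sv_scans: list[sel.OutlierScan] | None = None
    beta_scores: pd.DataFrame | None = None
    pseudo_beta: pd.DataFrame | None = None
    group_test: sel.GroupComparison | None = None


def _require(result, attr: str, needed_by: str):
    v = getattr(result, attr)
    if v is None:
        raise RuntimeError(
            f"stage '{needed_by}' needs '{attr}' but its producing stage was not run"
        )
    return v


def run_pipeline(config: RunConfig, outdir: str | None = None) -> PipelineResult:
    """Execute the configured stages in order and assemble the manifest."""
    notes = config.validate()
    for n in notes:
        logger.warning(n)
    manifest: dict = {"seed": config.sim.seed, "stages": list(config.stages),
                      "datasets": {}, "timings_s": {}}
    result = PipelineResult(manifest=manifest)
    stages = set(config.stages)

    def timed(name):
        t0 = time.time()

        def done():
            manifest["timings_s"][name] = round(time.time() - t0, 3)

        return done

    if "simulate" in stages:
        fin = timed("simulate")
        genome, truth, calls = Simulation(config.sim).run()
        result.genome, result.truth = genome, truth
        popmap = truth.population_map()
        result._calls = calls  # per (sample, caller) raw call lists
        manifest["datasets"]["true_snps"] = len(truth.snps)
        manifest["datasets"]["true_svs"] = len(truth.svs)
        fin()

    if "merge" in stages:
        fin = timed("merge")
        truth = _require(result, "truth", "merge")
        calls = getattr(result, "_calls", None)
        if calls is None:
            raise RuntimeError("stage 'merge' needs caller call sets from stage 'simulate'")
        per_sample = {}
        n_pass_calls = 0
        for sample in truth.samples["sample"]:
            callsets = []
            for prof in config.sim.caller_profiles:
                recs = [r for r in calls[(sample, prof.name)] if r.filter == "PASS"]
                n_pass_calls += len(recs)
                callsets.append(recs)
            per_sample[sample] = merge_per_sample(callsets, config.merge_params, sample=sample)
        cohort = merge_across_samples(per_sample, config.merge_params)
        result.cohort_svs = cohort
        result.unfiltered_sv = build_matrix([c.to_record() for c in cohort],
                                            truth.population_map())
        manifest["datasets"]["pass_caller_calls"] = n_pass_calls
        manifest["datasets"]["per_sample_consensus"] = sum(len(v) for v in per_sample.values())
        manifest["datasets"]["unfiltered_sv"] = len(cohort)
        fin()

    if "filter" in stages:
        fin = timed("filter")
        truth = _require(result, "truth", "filter")
        unfiltered = _require(result, "unfiltered_sv", "filter")
        popgen_sv = filt.filter_missing_maf(unfiltered, config.filter_params)
        result.popgen_sv = popgen_sv
        snp_matrix = build_matrix(truth.snp_records(), truth.population_map())
        snp_mm = filt.filter_missing_maf(snp_matrix, config.filter_params)
        wgs = filt.ld_prune(snp_mm, config.filter_params)
        thinned = filt.thin(wgs, config.filter_params.thin_distance)
        result.wgs_snp, result.thinned_snp = wgs, thinned
        kin = filt.relatedness_check(thinned, config.filter_params.kinship_flag)
        d = manifest["datasets"]
        d["raw_snp"] = snp_matrix.n_sites
        d["snp_missing_maf"] = snp_mm.n_sites
        d["wgs_snp"] = wgs.n_sites
        d["thinned_snp"] = thinned.n_sites
        d["popgen_sv"] = popgen_sv.n_sites
        d["sv_removed_missing_maf"] = unfiltered.n_sites - popgen_sv.n_sites
        manifest["kinship_max"] = float(np.nanmax(kin["kinship"])) if len(kin) else float("nan")
        manifest["kinship_flagged_pairs"] = int(kin["flagged"].sum())
        fin()

    if "landscape" in stages:
        fin = timed("landscape")
        genome = _require(result, "genome", "landscape")
        wgs = _require(result, "wgs_snp", "landscape")
        cohort = _require(result, "cohort_svs", "landscape")
        sv_records = [c.to_record() for c in cohort]
        windows = land.bin_counts(wgs.sites, sv_records, genome.chrom_lengths,
                                  bin_size=config.bin_size)
        reg = land.density_regression(windows)
        result.windows = windows.assign(fitted=reg.fitted, residual=reg.residuals)
        result.regression = reg
        result.enrichment = land.subtelomere_enrichment(
            windows, reg.residuals, genome.chrom_lengths, config.sim.subtelomere_frac)
        all_records = sv_records + [
            r for r in _snp_point_records(wgs)
        ]
        result.size_class_table = land.overlap_by_size_class(all_records, genome.genes)
        result.breakend_classes = land.classify_breakends(
            sv_records, genome.repeats, genome.chrom_lengths)
        popgen_sv = _require(result, "popgen_sv", "landscape")
        result.het_table, result.het_test = land.individual_heterozygosity(popgen_sv)
        manifest["glm_slope"] = reg.slope
        manifest["glm_t"] = reg.t_value
        manifest["repeat_breakend_fraction"] = land.repeat_fraction(result.breakend_classes)
        if result.enrichment:
            manifest["subtelomere_residual_diff"] = result.enrichment["difference"]
        fin()

    if "diversity" in stages:
        fin = timed("diversity")
        thinned = _require(result, "thinned_snp", "diversity")
        popgen_sv = _require(result, "popgen_sv", "diversity")
        result.diversity_snp = divmod_.diversity(thinned)
        result.diversity_sv = divmod_.diversity(popgen_sv)
        result.pca_snp = divmod_.pca(thinned)
        result.pca_sv = divmod_.pca(popgen_sv)
        truth = _require(result, "truth", "diversity")
        excluded = list(truth.samples.loc[
            truth.samples["population"].isin(config.excluded_pops), "sample"])
        inv_ids = divmod_.invader_specific(popgen_sv, list(config.invader_pops), excluded)
        keep_idx = np.flatnonzero(
            popgen_sv.samples["population"].isin(config.invader_pops).to_numpy())
        common_ids = divmod_.common_filter(inv_ids, popgen_sv, sample_idx=keep_idx)
        result.invader_specific_ids = inv_ids
        result.common_invader_ids = common_ids
        genome = _require(result, "genome", "diversity")
        sv_records = [c.to_record() for c in _require(result, "cohort_svs", "diversity")]
        popgen_ids = set(popgen_sv.sites["id"])
        popgen_records = [r for r in sv_records if r.variant_id in popgen_ids]
        classes = divmod_.classify_gene_overlap(popgen_records, genome.genes)
        order = {r.variant_id: c for r, c in zip(popgen_records, classes)}
        labels = [order[i] for i in popgen_sv.sites["id"]]
        result.sfs = divmod_.folded_sfs(popgen_sv, labels)
        manifest["datasets"]["invader_specific_sv"] = len(inv_ids)
        manifest["datasets"]["common_invader_specific_sv"] = len(common_ids)
        fin()

    if "selection" in stages:
        fin = timed("selection")
        thinned = _require(result, "thinned_snp", "selection")
        popgen_sv = _require(result, "popgen_sv", "selection")
        wgs = _require(result, "wgs_snp", "selection")
        snp_scans, sv_scans = [], []
        snp_out: set[str] = set()
        sv_out: set[str] = set()
        for k, sub in enumerate(config.invader_subgroups):
            g1 = thinned.population_index(config.native_pop)
            g2 = thinned.population_index(sub)
            scan = sel.pod_threshold(thinned, g1, g2, n_pod=config.n_pod,
                                     quantile=config.pod_quantile,
                                     seed=config.sim.seed + 1000 + k,
                                     contrast=f"{config.native_pop}-{sub}")
            snp_scans.append(scan)
            snp_out |= set(thinned.sites.loc[scan.flags, "id"])
            g1 = popgen_sv.population_index(config.native_pop)
            g2 = popgen_sv.population_index(sub)
            scan = sel.pod_threshold(popgen_sv, g1, g2, n_pod=config.n_pod,
                                     quantile=config.pod_quantile,
                                     seed=config.sim.seed + 2000 + k,
                                     contrast=f"{config.native_pop}-{sub}")
            sv_scans.append(scan)
            sv_out |= set(popgen_sv.sites.loc[scan.flags, "id"])
        result.snp_scans, result.sv_scans = snp_scans, sv_scans
        beta = sel.beta_scan(wgs, population=config.native_pop,
                             window=config.beta_window, min_maf=config.beta_min_maf)
        result.beta_scores = beta
        sv_records = [c.to_record() for c in _require(result, "cohort_svs", "selection")]
        popgen_ids = set(popgen_sv.sites["id"])
        popgen_records = [r for r in sv_records if r.variant_id in popgen_ids]
        pseudo = sel.pseudo_beta(popgen_records, beta, mode="per_sv_trimmed",
                                 window=config.beta_window)
        result.pseudo_beta = pseudo
        try:
            result.group_test = sel.group_comparison(
                sel.seven_groups(beta, snp_out, pseudo, sv_out))
        except ValueError as exc:
            logger.warning("group comparison skipped: %s", exc)
        manifest["datasets"]["outlier_snps"] = len(snp_out)
        manifest["datasets"]["outlier_svs"] = len(sv_out)
        manifest["datasets"]["beta_cores"] = len(beta)
        if result.group_test is not None:
            manifest["kruskal_H"] = result.group_test.H
            manifest["kruskal_df"] = result.group_test.df
            manifest["kruskal_p"] = result.group_test.p_value
        fin()

    if outdir is not None:
        _write_outputs(result, config, outdir)
    return result


def _snp_point_records(matrix: GenotypeMatrix):
    from svpopgen.vcfio import VariantRecord

    for row in matrix.sites.itertuples():
        yield VariantRecord(chrom=row.chrom, pos=int(row.pos), sv_type="SNP",
                            genotypes={}, length=1, variant_id=row.id)


def _write_outputs(result: PipelineResult, config: RunConfig, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if result.cohort_svs is not None:
        extra = {
            c.variant_id: {"SUPP": max(len(s) for s in c.support.values()) if c.support else 0,
                           "CALLERS": ",".join(sorted(set().union(*c.support.values())))
                           if c.support else "."}
            for c in result.cohort_svs
        }
        write_vcf([c.to_record() for c in result.cohort_svs], str(out / "unfiltered_sv.vcf"),
                  samples=list(result.truth.samples["sample"]) if result.truth is not None else None,
                  contigs=result.genome.chrom_lengths if result.genome is not None else None,
                  extra_info=extra)
    for name in ("windows", "size_class_table", "breakend_classes", "het_table",
                 "diversity_snp", "diversity_sv", "sfs", "beta_scores", "pseudo_beta"):
        df = getattr(result, name)
        if df is not None:
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if result.group_test is not None:
        result.group_test.group_summary.to_csv(out / "group_summary.tsv", sep="\t", index=False)
        result.group_test.dunn.to_csv(out / "dunn.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=float)
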