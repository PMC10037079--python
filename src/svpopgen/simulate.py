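"""Seeded generator for every input the analysis pipeline consumes.

The generator emulates the design of a multi-continent invasion study: a
small multi-chromosome genome with gene and repeat annotations; a cohort of
populations with a native source, invasive demes, and one extreme-drift
range-edge deme; population-structured SNPs and SVs; and three imperfect
SV pseudo-callers that introduce positional jitter, genotype error and
caller-specific false positives.

Population allele frequencies follow the Balding–Nichols model: an ancestral
frequency ``p`` is drawn per locus, and each population's frequency is drawn
from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with its drift parameter ``F``; sample
genotypes are then binomial draws.  Selection signals are planted on top:
balanced clusters (a core SNP at folded frequency ~0.4 with companion SNPs at
nearly the same folded frequency within +-1 kb), divergent loci (native vs
invasive frequency difference >= 0.6), and invader-specific SVs (alternate
allele absent from the native range).

Randomness: one global seed; every operation draws from a named substream so
that, e.g., adding false positives does not shift genotype draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from svpopgen.vcfio import SV_TYPES, VariantRecord, write_vcf

REPEAT_CLASSES = ("simple", "low_complexity", "LINE", "LTR", "unclassified")
_REPEAT_WEIGHTS = (0.45, 0.15, 0.15, 0.15, 0.10)
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent of draws made under other names."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one pseudo-caller.

    ``detect_prob`` may be a single probability or a per-SV-type map;
    ``false_positive_rate`` is per Mb of genome per sample.
    """

    name: str
    detect_prob: float | dict[str, float] = 0.85
    pos_jitter_bp: int = 100
    genotype_error_rate: float = 0.02
    false_positive_rate: float = 2.0
    pass_filter_prob: float = 0.92

    def detect_p(self, sv_type: str) -> float:
        if isinstance(self.detect_prob, dict):
            return float(self.detect_prob.get(sv_type, 0.0))
        return float(self.detect_prob)

    def validate(self) -> None:
        if not 0 <= self.pos_jitter_bp < 1000:
            raise ValueError("pos_jitter_bp must be in [0, 1000) so replicate calls stay mergeable")
        probs = (
            list(self.detect_prob.values()) if isinstance(self.detect_prob, dict) else [self.detect_prob]
        )
        for p in probs + [self.genotype_error_rate, self.pass_filter_prob]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1] in caller {self.name}")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")


def identity_profiles() -> list[CallerProfile]:
    """Three error-free callers: downstream merging must recover truth exactly."""
    return [
        CallerProfile(n, detect_prob=1.0, pos_jitter_bp=0, genotype_error_rate=0.0,
                      false_positive_rate=0.0, pass_filter_prob=1.0)
        for n in ("callerA", "callerB", "callerC")
    ]


def default_profiles() -> list[CallerProfile]:
    return [
        CallerProfile("callerA", detect_prob=0.88, pos_jitter_bp=120,
                      genotype_error_rate=0.02, false_positive_rate=2.0, pass_filter_prob=0.93),
        CallerProfile("callerB", detect_prob=0.82, pos_jitter_bp=60,
                      genotype_error_rate=0.03, false_positive_rate=3.0, pass_filter_prob=0.90),
        CallerProfile("callerC", detect_prob={"DEL": 0.85, "DUP": 0.75, "INV": 0.6,
                                              "INS": 0.55, "TRA": 0.7},
                      pos_jitter_bp=150, genotype_error_rate=0.04,
                      false_positive_rate=4.0, pass_filter_prob=0.88),
    ]


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_samples: int
    fst: float  # Balding-Nichols drift parameter F in [0, 1)
    batch: str = "b1"
    role: str = "invasive"  # 'native', 'invasive', or 'range_edge'


def study_populations() -> list[PopulationSpec]:
    """The cohort design emulated by default: 8 native, 8 + 24 invasive, 9 range-edge."""
    return [
        PopulationSpec("UK", 8, 0.03, batch="b1", role="native"),
        PopulationSpec("NA", 8, 0.08, batch="b1", role="invasive"),
        PopulationSpec("AU_EAST", 12, 0.12, batch="b2", role="invasive"),
        PopulationSpec("AU_SOUTH", 12, 0.12, batch="b2", role="invasive"),
        PopulationSpec("MUNG", 9, 0.40, batch="b2", role="range_edge"),
    ]


@dataclass
class SimConfig:
    """Full parameterization of one simulated study.

    Defaults mirror the emulated study design at desk scale: a 4.5-Mb
    three-chromosome genome, 49 samples in five demes, SNP density of the
    order of the study's high-density callset, and SV density high enough to
    power the SV-side statistics.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (2_000_000, 1_500_000, 1_000_000)
    populations: list[PopulationSpec] = field(default_factory=study_populations)
    n_snps: int = 20_000
    n_svs: int = 300
    sv_type_weights: dict[str, float] = field(
        default_factory=lambda: {"DEL": 0.45, "TRA": 0.25, "DUP": 0.18, "INV": 0.07, "INS": 0.05}
    )
    sv_length_range: tuple[int, int] = (30, 10_000)  # log-uniform
    gene_density: float = 10.0  # genes per Mb
    repeat_density: float = 300.0  # repeat intervals per Mb (~8% genome coverage)
    subtelomere_frac: float = 0.10
    sv_subtelomere_enrichment: float = 3.0
    caller_profiles: list[CallerProfile] = field(default_factory=default_profiles)
    n_balanced_loci: int = 3
    n_companion_snps: int = 12
    n_divergent_loci: int = 20
    invader_specific_sv_frac: float = 0.15
    batch_sv_dropout: dict[str, float] = field(default_factory=dict)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    min_sv_spacing: int = 2500  # keeps distinct true SV loci outside the 1-kb merge radius
    density_field_sd: float = 0.6  # log-sd of the shared SNP/SV density field
    density_tile: int = 100_000  # tile size of the latent density field
    balanced_frac_upstream_dels: float = 0.0  # fraction of balanced clusters planted just upstream of a DEL
    sv_invader_admixture: bool = False  # invasive SV input as a two-source mixture
    gene_length_range: tuple[int, int] = (500, 5_000)
    repeat_length_range: tuple[int, int] = (50, 500)

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def genome_mb(self) -> float:
        return sum(self.chrom_lengths) / 1e6

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for pop in self.populations:
            for i in range(pop.n_samples):
                rows.append(
                    {"sample": f"{pop.name}_{i + 1:02d}", "population": pop.name,
                     "batch": pop.batch, "role": pop.role}
                )
        return pd.DataFrame(rows)

    def validate(self) -> None:
        if self.n_chrom < 1:
            raise ValueError("need at least one chromosome")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 <= self.subtelomere_frac < 0.5:
            raise ValueError("subtelomere_frac must be in [0, 0.5): each chromosome must be "
                             "longer than twice its subtelomere window")
        if self.sv_subtelomere_enrichment < 1.0:
            raise ValueError("sv_subtelomere_enrichment must be >= 1")
        w = sum(self.sv_type_weights.get(t, 0.0) for t in SV_TYPES)
        if abs(w - 1.0) > 1e-8:
            raise ValueError(f"sv_type_weights must sum to 1 (got {w})")
        if self.sv_length_range[0] < 30:
            raise ValueError("minimum SV length is 30 bp")
        if self.sv_length_range[1] < self.sv_length_range[0]:
            raise ValueError("bad sv_length_range")
        for pop in self.populations:
            if not 0.0 <= pop.fst < 1.0:
                raise ValueError(f"population {pop.name}: F must be in [0, 1)")
            if pop.n_samples < 1:
                raise ValueError(f"population {pop.name}: n_samples must be >= 1")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
        if len(self.caller_profiles) != 3:
            raise ValueError("exactly three caller profiles are expected")
        for prof in self.caller_profiles:
            prof.validate()
        for b, d in self.batch_sv_dropout.items():
            if not 0.0 <= d < 1.0:
                raise ValueError(f"batch {b}: dropout must be in [0, 1)")


@dataclass
class Genome:
    """Simulated genome bundle: sequences plus gene and repeat annotations."""

    chrom_lengths: dict[str, int]
    sequences: dict[str, np.ndarray]  # S1 byte arrays
    genes: pd.DataFrame  # chrom, start, end, feature_id (0-based half-open)
    repeats: pd.DataFrame  # chrom, start, end, feature_id (= repeat class label)

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                s = seq.tobytes().decode()
                for i in range(0, len(s), width):
                    fh.write(s[i:i + width] + "\n")

    def write_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in self.genes.iterrows():
                fh.write(
                    f"{g.chrom}\tsvpopgen_sim\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                    f"ID={g.feature_id}\n"
                )

    def write_repeats_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for _, r in self.repeats.iterrows():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.feature_id}\n")


def simulate_genome(config: SimConfig) -> Genome:
    """Generate sequences, non-overlapping gene spans, and repeat intervals."""
    config.validate()
    seq_rng = _rng(config.seed, "genome.sequence")
    gene_rng = _rng(config.seed, "genome.genes")
    rep_rng = _rng(config.seed, "genome.repeats")
    lengths = dict(zip(config.chrom_names, config.chrom_lengths))
    sequences = {c: _BASES[seq_rng.integers(0, 4, size=l)] for c, l in lengths.items()}

    gene_rows = []
    for chrom, L in lengths.items():
        n = gene_rng.poisson(config.gene_density * L / 1e6)
        glo, ghi = config.gene_length_range
        lens = np.exp(gene_rng.uniform(np.log(glo), np.log(ghi), size=n)).astype(int)
        starts = np.sort(gene_rng.integers(0, max(1, L - ghi), size=n))
        last_end = -1
        for k, (s, ln) in enumerate(zip(starts, lens)):
            if s <= last_end:  # keep genes non-overlapping
                continue
            e = min(s + ln, L)
            gene_rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                              "feature_id": f"gene_{chrom}_{k}"})
            last_end = e
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "feature_id"])

    rep_rows = []
    for chrom, L in lengths.items():
        n = rep_rng.poisson(config.repeat_density * L / 1e6)
        rlo, rhi = config.repeat_length_range
        lens = rep_rng.integers(rlo, rhi + 1, size=n)
        starts = rep_rng.integers(0, max(1, L - rhi), size=n)
        classes = rep_rng.choice(REPEAT_CLASSES, size=n, p=_REPEAT_WEIGHTS)
        for s, ln, cl in zip(np.sort(starts), lens[np.argsort(starts)], classes):
            rep_rows.append({"chrom": chrom, "start": int(s), "end": int(min(s + ln, L)),
                             "feature_id": str(cl)})
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "feature_id"])
    return Genome(lengths, sequences, genes, repeats)


@dataclass
class TruthSet:
    """Ground-truth variants, per-population frequencies, and genotypes."""

    samples: pd.DataFrame  # sample, population, batch, role
    snps: pd.DataFrame  # chrom, pos, id, ref, alt, flags + freq_<pop> columns
    svs: pd.DataFrame  # chrom, pos, end, length, type, strands, id, invader_specific + freqs
    snp_genotypes: np.ndarray  # n_snps x n_samples dosages
    sv_genotypes: np.ndarray  # n_svs x n_samples dosages

    def population_map(self) -> pd.DataFrame:
        return self.samples[["sample", "population", "batch"]]

    def sv_records(self) -> list[VariantRecord]:
        return _records_from_table(self.svs, self.sv_genotypes, self.samples, sv=True)

    def snp_records(self) -> list[VariantRecord]:
        return _records_from_table(self.snps, self.snp_genotypes, self.samples, sv=False)


def _records_from_table(table: pd.DataFrame, genotypes: np.ndarray,
                        samples: pd.DataFrame, sv: bool) -> list[VariantRecord]:
    ids = list(samples["sample"])
    out = []
    for i, row in enumerate(table.itertuples()):
        gts = {s: int(genotypes[i, k]) for k, s in enumerate(ids)}
        if sv:
            rec = VariantRecord(
                chrom=row.chrom, pos=int(row.pos), sv_type=row.type, genotypes=gts,
                end=int(row.end) if pd.notna(row.end) else None,
                length=int(row.length) if pd.notna(row.length) else None,
                strands=row.strands, variant_id=row.id,
            )
        else:
            rec = VariantRecord(chrom=row.chrom, pos=int(row.pos), sv_type="SNP",
                                genotypes=gts, length=1, variant_id=row.id,
                                ref=row.ref, alt=row.alt)
        out.append(rec)
    return out


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    if F <= 0.0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _tile_table(config: SimConfig, seed_name: str = "variants.field"):
    """Latent density field shared by SNPs and SVs.

    The genome is tiled (``density_tile`` bp); each tile gets a log-normal
    weight with log-sd ``density_field_sd``.  Both variant classes draw
    positions proportional to the weights, which is what makes their window
    densities genuinely correlated, as in real genomes where mutation and
    ascertainment processes covary along the sequence.
    """
    rng = _rng(config.seed, seed_name)
    chroms, starts, lens, weights = [], [], [], []
    for ci, L in enumerate(config.chrom_lengths):
        n_tiles = int(np.ceil(L / config.density_tile))
        w = np.exp(rng.normal(0.0, config.density_field_sd, size=n_tiles)) \
            if config.density_field_sd > 0 else np.ones(n_tiles)
        for t in range(n_tiles):
            s = t * config.density_tile
            chroms.append(ci)
            starts.append(s)
            lens.append(min(config.density_tile, L - s))
            weights.append(w[t])
    chroms = np.array(chroms)
    starts = np.array(starts)
    lens = np.array(lens, dtype=float)
    mass = np.array(weights) * lens
    return chroms, starts, lens, mass / mass.sum()


def _draw_field_position(rng: np.random.Generator, tiles) -> tuple[int, int]:
    chroms, starts, lens, p = tiles
    t = rng.choice(len(p), p=p)
    return int(chroms[t]), int(starts[t] + rng.integers(0, int(lens[t])) + 1)


def _is_subtelomeric(pos: int, L: int, frac: float) -> bool:
    w = frac * L
    return pos <= w or pos > L - w


def simulate_population_variants(config: SimConfig, genome: Genome) -> TruthSet:
    """Draw true SNPs and SVs with population structure and planted signals."""
    config.validate()
    samples = config.sample_table()
    pops = config.populations
    pop_of = samples["population"].to_numpy()
    native = [p.name for p in pops if p.role == "native"]
    invasive_core = [p.name for p in pops if p.role == "invasive"]
    native_f = min((p.fst for p in pops if p.role == "native"), default=0.0)
    tiles = _tile_table(config)
    lo, hi = config.ancestral_freq_range

    # ---- SV loci first (balanced clusters may be planted upstream of DELs) --
    sv_rng = _rng(config.seed, "sv.positions")
    type_rng = _rng(config.seed, "sv.types")
    types = list(SV_TYPES)
    weights = np.array([config.sv_type_weights.get(t, 0.0) for t in types])
    mult = config.sv_subtelomere_enrichment
    sv_rows = []
    taken: dict[str, list[int]] = {c: [] for c in config.chrom_names}
    attempts = 0
    while len(sv_rows) < config.n_svs and attempts < config.n_svs * 500:
        attempts += 1
        ci, pos = _draw_field_position(sv_rng, tiles)
        chrom, L = config.chrom_names[ci], config.chrom_lengths[ci]
        # accept-reject for subtelomeric enrichment on top of the shared field
        m = mult if _is_subtelomeric(pos, L, config.subtelomere_frac) else 1.0
        if sv_rng.random() >= m / mult:
            continue
        sv_type = type_rng.choice(types, p=weights)
        llo, lhi = config.sv_length_range
        length = int(np.exp(type_rng.uniform(np.log(llo), np.log(lhi))))
        if sv_type == "TRA":
            length, end = None, None
        elif sv_type == "INS":
            end = None
        else:
            end = pos + length - 1
            if end >= L:
                continue
        if any(abs(pos - q) < config.min_sv_spacing for q in taken[chrom]):
            continue
        strands = {"DEL": "+-", "DUP": "-+", "INV": "++", "INS": "+-", "TRA": "+-"}[sv_type]
        taken[chrom].append(pos)
        sv_rows.append({"chrom": chrom, "pos": pos, "end": end, "length": length,
                        "type": sv_type, "strands": strands})
    svs = pd.DataFrame(sv_rows)
    n_svs = len(svs)

    # ---- SNP positions: shared density field, unique (chrom, pos) ---------
    pos_rng = _rng(config.seed, "snp.positions")
    seen: set[tuple[int, int]] = set()
    snp_chrom_l: list[str] = []
    snp_pos_l: list[int] = []
    guard = 0
    while len(snp_pos_l) < config.n_snps and guard < config.n_snps * 50:
        guard += 1
        ci, pos = _draw_field_position(pos_rng, tiles)
        if (ci, pos) in seen:
            continue
        seen.add((ci, pos))
        snp_chrom_l.append(config.chrom_names[ci])
        snp_pos_l.append(pos)
    snp_chrom = np.array(snp_chrom_l)
    snp_pos = np.array(snp_pos_l, dtype=np.int64)
    n_snps = len(snp_pos)
    balanced_core = np.zeros(n_snps, dtype=bool)
    balanced_companion = np.zeros(n_snps, dtype=bool)
    divergent = np.zeros(n_snps, dtype=bool)

    # ---- balanced clusters: new positions so companion density is guaranteed
    flag_rng = _rng(config.seed, "snp.flags")
    del_pool = [(r.chrom, int(r.pos)) for r in svs.itertuples()
                if r.type == "DEL" and r.pos > 1100]
    extra_chrom, extra_pos, extra_core, extra_comp = [], [], [], []
    for b in range(config.n_balanced_loci):
        k = config.n_companion_snps
        if del_pool and flag_rng.random() < config.balanced_frac_upstream_dels:
            chrom, dpos = del_pool.pop(int(flag_rng.integers(0, len(del_pool))))
            # cluster confined to the 1-kb window upstream of the DEL start
            window = np.arange(dpos - 1000, dpos)
            picks = flag_rng.choice(window, size=k + 1, replace=False)
        else:
            chrom = config.chrom_names[b % config.n_chrom]
            Lc = config.chrom_lengths[b % config.n_chrom]
            core = int(flag_rng.uniform(0.2, 0.8) * Lc)
            offs = flag_rng.choice(np.arange(-1000, 1001), size=k + 4, replace=False)
            offs = offs[offs != 0][:k]
            picks = np.concatenate([[core], core + offs])
        extra_chrom += [chrom] * len(picks)
        extra_pos += [int(x) for x in picks]
        extra_core += [True] + [False] * (len(picks) - 1)
        extra_comp += [False] + [True] * (len(picks) - 1)

    if extra_pos:
        snp_chrom = np.concatenate([snp_chrom, np.array(extra_chrom)])
        snp_pos = np.concatenate([snp_pos, np.array(extra_pos, dtype=np.int64)])
        balanced_core = np.concatenate([balanced_core, np.array(extra_core)])
        balanced_companion = np.concatenate([balanced_companion, np.array(extra_comp)])
        divergent = np.concatenate([divergent, np.zeros(len(extra_pos), dtype=bool)])
        n_snps = len(snp_pos)

    neutral_idx = np.flatnonzero(~(balanced_core | balanced_companion))
    div_idx = flag_rng.choice(neutral_idx, size=min(config.n_divergent_loci, len(neutral_idx)),
                              replace=False)
    divergent[div_idx] = True

    # ---- SNP frequencies ---------------------------------------------------
    freq_rng = _rng(config.seed, "snp.frequencies")
    p_anc = freq_rng.uniform(lo, hi, size=n_snps)
    freqs = np.column_stack([_balding_nichols(freq_rng, p_anc, pop.fst) for pop in pops])

    # balanced clusters: folded frequency ~0.4 (core), companions within 0.05,
    # shared across populations (balancing selection maintains the polymorphism)
    for core_i in np.flatnonzero(balanced_core):
        chrom, cpos = snp_chrom[core_i], snp_pos[core_i]
        members = np.flatnonzero(
            (snp_chrom == chrom) & (np.abs(snp_pos - cpos) <= 1000)
            & (balanced_core | balanced_companion)
        )
        f_core = 0.4
        for m in members:
            f = f_core if m == core_i else float(np.clip(
                f_core + freq_rng.uniform(-0.05, 0.05), 0.16, 0.5))
            unfolded = f if freq_rng.random() < 0.5 else 1.0 - f
            freqs[m, :] = unfolded

    # divergent loci: native low / invasive high (or flipped), |dp| >= 0.6
    for i in np.flatnonzero(divergent):
        low = freq_rng.uniform(0.02, 0.15)
        high = freq_rng.uniform(low + 0.6, 0.98)
        flip = freq_rng.random() < 0.5
        for k, pop in enumerate(pops):
            is_nat = pop.role == "native"
            freqs[i, k] = (low if is_nat else high) if not flip else (high if is_nat else low)

    gt_rng = _rng(config.seed, "snp.genotypes")
    pop_col = {pop.name: k for k, pop in enumerate(pops)}
    sample_pop_idx = np.array([pop_col[p] for p in pop_of])
    snp_gt = gt_rng.binomial(2, freqs[:, sample_pop_idx]).astype(np.int16)

    bases = np.array(list("ACGT"))
    ref_i = _rng(config.seed, "snp.alleles").integers(0, 4, size=n_snps)
    alt_i = (ref_i + _rng(config.seed, "snp.alleles2").integers(1, 4, size=n_snps)) % 4

    order = np.lexsort((snp_pos, snp_chrom))
    snps = pd.DataFrame(
        {
            "chrom": snp_chrom[order], "pos": snp_pos[order],
            "id": [f"snp{j}" for j in range(n_snps)],
            "ref": bases[ref_i[order]], "alt": bases[alt_i[order]],
            "balanced_core": balanced_core[order],
            "balanced_companion": balanced_companion[order],
            "divergent": divergent[order],
        }
    )
    for k, pop in enumerate(pops):
        snps[f"freq_{pop.name}"] = freqs[order, k]
    snp_gt = snp_gt[order]

    # ---- SV frequencies ----------------------------------------------------
    n_inv = int(np.floor(config.invader_specific_sv_frac * n_svs))
    inv_idx = _rng(config.seed, "sv.invader").choice(n_svs, size=n_inv, replace=False)
    invader_specific = np.zeros(n_svs, dtype=bool)
    invader_specific[inv_idx] = True

    svf_rng = _rng(config.seed, "sv.frequencies")
    p_anc_sv = svf_rng.uniform(lo, hi, size=n_svs)
    sv_cols = []
    for pop in pops:
        if config.sv_invader_admixture and pop.role == "invasive":
            # SV input assembled from two independent introductions of source
            # stock: the mixture halves the drift variance relative to one
            # draw at the source's F, raising SV diversity in the invader
            draw1 = _balding_nichols(svf_rng, p_anc_sv, native_f)
            draw2 = _balding_nichols(svf_rng, p_anc_sv, native_f)
            sv_cols.append(0.5 * (draw1 + draw2))
        else:
            sv_cols.append(_balding_nichols(svf_rng, p_anc_sv, pop.fst))
    sv_freqs = np.column_stack(sv_cols)
    for i in np.flatnonzero(invader_specific):
        for k, pop in enumerate(pops):
            if pop.role == "native":
                sv_freqs[i, k] = 0.0
            else:  # newly arisen in the invasion: mostly rare
                sv_freqs[i, k] = svf_rng.uniform(0.02, 0.3)

    svgt_rng = _rng(config.seed, "sv.genotypes")
    sv_gt = svgt_rng.binomial(2, sv_freqs[:, sample_pop_idx]).astype(np.int16)

    # ascertainment guarantees: labelled SVs segregate in core invasive demes;
    # unlabelled SVs segregate in the native range (the discovery cohort spans
    # all demes, so observed invader-specificity matches the truth labels)
    nat_cols = np.flatnonzero(np.isin(pop_of, native))
    inv_cols = np.flatnonzero(np.isin(pop_of, invasive_core))
    for i in range(n_svs):
        if invader_specific[i]:
            if sv_gt[i, inv_cols].sum() == 0:
                k = svgt_rng.integers(0, len(inv_cols))
                sv_gt[i, inv_cols[k]] = 1
            sv_gt[i, nat_cols] = 0
        else:
            if sv_gt[i, nat_cols].sum() == 0:
                k = svgt_rng.integers(0, len(nat_cols))
                sv_gt[i, nat_cols[k]] = 1

    order = np.lexsort((svs["pos"].to_numpy(), svs["chrom"].to_numpy()))
    svs = svs.iloc[order].reset_index(drop=True)
    svs["id"] = [f"sv{j}" for j in range(n_svs)]
    svs["invader_specific"] = invader_specific[order]
    for k, pop in enumerate(pops):
        svs[f"freq_{pop.name}"] = sv_freqs[order, k]
    sv_gt = sv_gt[order]

    return TruthSet(samples=samples, snps=snps, svs=svs,
                    snp_genotypes=snp_gt, sv_genotypes=sv_gt)


def emulate_callers(
    truth: TruthSet,
    profiles: list[CallerProfile],
    seed: int,
    config: SimConfig,
) -> dict[tuple[str, str], list[VariantRecord]]:
    """Imperfect per-sample, per-caller SV call sets from the truth.

    A caller emits a call for a sample only where the sample carries the SV
    (dosage >= 1) and detection succeeds; positions are jittered (interval
    shifted, so SVLEN is preserved), genotypes corrupted between 0/1 and 1/1
    at the profile's error rate, and Poisson false positives added uniformly.
    Batch-dependent dropout (``config.batch_sv_dropout``) removes a true SV
    from every caller of an affected sample.
    """
    for prof in profiles:
        prof.validate()
    samples = truth.samples
    sv_table = truth.svs
    calls: dict[tuple[str, str], list[VariantRecord]] = {}
    drop_rng = _rng(seed, "callers.dropout")
    dropout = {
        (s, i): drop_rng.random() < config.batch_sv_dropout.get(b, 0.0)
        for _, (s, b) in samples[["sample", "batch"]].iterrows()
        for i in range(len(sv_table))
    } if config.batch_sv_dropout else {}

    types = list(SV_TYPES)
    weights = np.array([config.sv_type_weights.get(t, 0.0) for t in types])
    for prof in profiles:
        det_rng = _rng(seed, f"callers.{prof.name}.detect")
        fp_rng = _rng(seed, f"callers.{prof.name}.fp")
        for col, sample in enumerate(samples["sample"]):
            out: list[VariantRecord] = []
            for i, row in enumerate(sv_table.itertuples()):
                dosage = int(truth.sv_genotypes[i, col])
                if dosage <= 0 or dropout.get((sample, i), False):
                    continue
                if det_rng.random() >= prof.detect_p(row.type):
                    continue
                jit = int(det_rng.integers(-prof.pos_jitter_bp, prof.pos_jitter_bp + 1)) \
                    if prof.pos_jitter_bp else 0
                jit = max(jit, 1 - int(row.pos))  # keep the shifted interval on the chromosome
                gt = dosage
                if det_rng.random() < prof.genotype_error_rate:
                    gt = 3 - dosage  # flip 0/1 <-> 1/1
                filt = "PASS" if det_rng.random() < prof.pass_filter_prob else "LowQual"
                pos = max(1, int(row.pos) + jit)
                end = int(row.end) + jit if pd.notna(row.end) else None
                out.append(VariantRecord(
                    chrom=row.chrom, pos=pos, sv_type=row.type, genotypes={sample: gt},
                    end=end, length=int(row.length) if pd.notna(row.length) else None,
                    strands=row.strands, filter=filt, caller=prof.name,
                    variant_id=f"{prof.name}_{sample}_{row.id}",
                ))
            n_fp = fp_rng.poisson(prof.false_positive_rate * config.genome_mb)
            for k in range(n_fp):
                ci = fp_rng.choice(len(config.chrom_lengths),
                                   p=np.array(config.chrom_lengths) / sum(config.chrom_lengths))
                L = config.chrom_lengths[ci]
                sv_type = fp_rng.choice(types, p=weights)
                llo, lhi = config.sv_length_range
                length = int(np.exp(fp_rng.uniform(np.log(llo), np.log(lhi))))
                pos = int(fp_rng.integers(1, max(2, L - length)))
                end = pos + length - 1 if sv_type in ("DEL", "DUP", "INV") else None
                length_out = None if sv_type == "TRA" else length
                gt = int(fp_rng.integers(1, 3))
                filt = "PASS" if fp_rng.random() < prof.pass_filter_prob else "LowQual"
                strands = {"DEL": "+-", "DUP": "-+", "INV": "++", "INS": "+-", "TRA": "+-"}[sv_type]
                out.append(VariantRecord(
                    chrom=config.chrom_names[ci], pos=pos, sv_type=str(sv_type),
                    genotypes={sample: gt}, end=end, length=length_out, strands=strands,
                    filter=filt, caller=prof.name, variant_id=f"{prof.name}_{sample}_fp{k}",
                ))
            out.sort(key=lambda r: (r.chrom, r.pos))
            calls[(sample, prof.name)] = out
    return calls


@dataclass
class Simulation:
    """End-to-end generator: genome, truth, caller VCFs, and on-disk bundle."""

    config: SimConfig

    def run(self) -> tuple[Genome, TruthSet, dict[tuple[str, str], list[VariantRecord]]]:
        genome = simulate_genome(self.config)
        truth = simulate_population_variants(self.config, genome)
        calls = emulate_callers(truth, self.config.caller_profiles, self.config.seed, self.config)
        return genome, truth, calls

    def write(self, outdir: str) -> dict[str, str]:
        """Write the full input bundle; returns a manifest of paths."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        genome, truth, calls = self.run()
        contigs = genome.chrom_lengths
        manifest: dict[str, str] = {}
        genome.write_fasta(out / "genome.fa")
        genome.write_gff3(out / "genes.gff3")
        genome.write_repeats_bed(out / "repeats.bed")
        manifest.update(genome_fasta=str(out / "genome.fa"), genes_gff3=str(out / "genes.gff3"),
                        repeats_bed=str(out / "repeats.bed"))
        truth.population_map().to_csv(out / "population_map.tsv", sep="\t", index=False)
        truth.snps.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
        truth.svs.to_csv(out / "truth_svs.tsv", sep="\t", index=False)
        manifest.update(population_map=str(out / "population_map.tsv"),
                        truth_snps=str(out / "truth_snps.tsv"),
                        truth_svs=str(out / "truth_svs.tsv"))
        write_vcf(truth.snp_records(), str(out / "snps.vcf"),
                  samples=list(truth.samples["sample"]), contigs=contigs)
        manifest["snp_vcf"] = str(out / "snps.vcf")
        caller_dir = out / "caller_vcfs"
        caller_dir.mkdir(exist_ok=True)
        for (sample, caller), recs in calls.items():
            p = caller_dir / f"{sample}.{caller}.vcf"
            write_vcf(recs, str(p), samples=[sample], contigs=contigs)
            manifest[f"calls:{sample}:{caller}"] = str(p)
        return manifest
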