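"""Genotype-aware consensus SV merging.

Two stages mirror the construction of a cohort SV callset from three
independent callers:

1. **Per-sample merge** — calls from the three callers for one sample are
   partitioned by genotype (0/0, 0/1, 1/1) and, within each partition, calls
   whose break ends lie within ``max_dist`` and whose type and strand agree
   are clustered; a cluster supported by at least ``min_support`` distinct
   callers becomes a consensus call carrying that genotype.  Requiring the
   cluster to form *within* a genotype partition is the genotype-agreement
   modification: callers must agree not only on the variant but on the
   individual's genotype.
2. **Cross-sample merge** — per-sample consensus calls are clustered across
   samples by the same distance/type/strand rule with ``min_support=1`` and
   no genotype requirement, yielding one cohort record per SV locus with a
   genotype per sample (samples with no member call are reference, 0/0, by
   default).

Clustering is defined by an explicit objective rather than by an incremental
heuristic: within each connected component (single-linkage reachability at
``max_dist``) the partition chosen is the one that (1) retains the most
calls, (2) uses the fewest clusters, (3) has the smallest total intra-cluster
pairwise distance, then breaks remaining ties lexicographically.  Components
of up to ``exact_component_limit`` calls are solved exactly; larger
components (common only in the cross-sample stage where dozens of samples
share a locus) fall back to a deterministic greedy clique-growing pass.
``brute_force_merge_oracle`` evaluates the same objective by exhaustive
enumeration and defines correctness on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from statistics import median_low

import numpy as np

from svpopgen.vcfio import MISSING, VariantRecord


@dataclass(frozen=True)
class MergeParams:
    max_dist: int = 1000
    min_support: int = 2
    require_type: bool = True
    require_strand: bool = True
    min_len: int = 30
    require_genotype_agreement: bool = True
    exact_component_limit: int = 10

    def __post_init__(self) -> None:
        if self.max_dist <= 0:
            raise ValueError("max_dist must be positive")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")

    def cross_sample(self) -> "MergeParams":
        """The cross-sample variant: support 1, no genotype requirement."""
        return replace(self, min_support=1, require_genotype_agreement=False)


@dataclass
class ConsensusSV:
    """A merged SV with per-sample genotypes and supporting-caller sets."""

    chrom: str
    pos: int
    sv_type: str
    genotypes: dict[str, int]
    end: int | None = None
    length: int | None = None
    strands: str | None = None
    support: dict[str, frozenset[str]] = field(default_factory=dict)
    member_ids: tuple[str, ...] = ()
    variant_id: str | None = None

    def to_record(self) -> VariantRecord:
        return VariantRecord(
            chrom=self.chrom, pos=self.pos, sv_type=self.sv_type,
            genotypes=dict(self.genotypes), end=self.end, length=self.length,
            strands=self.strands, variant_id=self.variant_id,
        )


@dataclass(frozen=True)
class _Call:
    """Uniform clustering item for both stages."""

    idx: int
    chrom: str
    pos: int
    end: int | None
    sv_type: str
    strands: str | None
    gt: int
    owner: str  # caller (per-sample stage) or sample (cross-sample stage)
    call_id: str
    length: int | None
    payload: object = None


def _pair_dist(a: _Call, b: _Call) -> int:
    d = abs(a.pos - b.pos)
    if a.end is not None and b.end is not None:
        d = max(d, abs(a.end - b.end))
    return d


def _compatible(a: _Call, b: _Call, params: MergeParams, require_gt: bool) -> bool:
    if a.chrom != b.chrom or a.owner == b.owner:
        return False
    if params.require_type and a.sv_type != b.sv_type:
        return False
    if params.require_strand and a.strands != b.strands:
        return False
    if require_gt and a.gt != b.gt:
        return False
    return _pair_dist(a, b) <= params.max_dist


def _cluster_valid(cluster: tuple[int, ...], compat: np.ndarray) -> bool:
    return all(compat[i, j] for i, j in itertools.combinations(cluster, 2))


def _score(partition: list[tuple[int, ...]], calls: list[_Call], params: MergeParams):
    """Objective tuple to MINIMIZE; identical for fast path and oracle."""
    retained = []
    total_dist = 0
    for c in partition:
        if len(c) >= params.min_support:
            retained.extend(c)
        for i, j in itertools.combinations(c, 2):
            total_dist += _pair_dist(calls[i], calls[j])
    canonical = tuple(sorted(tuple(sorted(c)) for c in partition))
    return (-len(retained), len(partition), total_dist, tuple(sorted(retained)), canonical)


def _enumerate_valid_partitions(n: int, compat: np.ndarray):
    """All partitions of range(n) whose clusters are pairwise compatible.

    Items are assigned in index order to an existing compatible cluster or a
    new one, so only valid partitions are generated.
    """
    partition: list[list[int]] = []

    def rec(i: int):
        if i == n:
            yield [tuple(c) for c in partition]
            return
        for c in partition:
            if all(compat[i, j] for j in c):
                c.append(i)
                yield from rec(i + 1)
                c.pop()
        partition.append([i])
        yield from rec(i + 1)
        partition.pop()

    yield from rec(0)


def _optimal_partition(calls: list[_Call], params: MergeParams, require_gt: bool):
    n = len(calls)
    compat = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        compat[i, j] = compat[j, i] = _compatible(calls[i], calls[j], params, require_gt)
    best = None
    best_part = None
    for part in _enumerate_valid_partitions(n, compat):
        s = _score(part, calls, params)
        if best is None or s < best:
            best, best_part = s, part
    return [tuple(sorted(c)) for c in best_part]


def _greedy_partition(calls: list[_Call], params: MergeParams, require_gt: bool):
    """Deterministic clique-growing fallback for large components."""
    order = sorted(range(len(calls)),
                   key=lambda i: (calls[i].pos, calls[i].end or calls[i].pos,
                                  calls[i].owner, calls[i].call_id))
    unassigned = set(order)
    clusters = []
    for seed in order:
        if seed not in unassigned:
            continue
        cluster = [seed]
        unassigned.discard(seed)
        for j in order:
            if j not in unassigned:
                continue
            if all(_compatible(calls[j], calls[k], params, require_gt) for k in cluster):
                cluster.append(j)
                unassigned.discard(j)
        clusters.append(tuple(sorted(cluster)))
    return clusters


def _components(calls: list[_Call], params: MergeParams, require_gt: bool):
    """Single-linkage components under the compatibility relation.

    Calls are pre-sorted by position; a gap larger than ``max_dist`` between
    consecutive positions separates components, and exact linkage is resolved
    within each candidate run.
    """
    order = sorted(range(len(calls)), key=lambda i: (calls[i].pos, calls[i].end or 0, i))
    runs: list[list[int]] = []
    for i in order:
        if runs and calls[i].pos - calls[runs[-1][-1]].pos <= params.max_dist:
            runs[-1].append(i)
        else:
            runs.append([i])
    for run in runs:
        if len(run) == 1:
            yield run
            continue
        parent = {i: i for i in run}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in itertools.combinations(run, 2):
            if _compatible(calls[a], calls[b], params, require_gt):
                parent[find(a)] = find(b)
        comps: dict[int, list[int]] = {}
        for i in run:
            comps.setdefault(find(i), []).append(i)
        for c in sorted(comps.values(), key=lambda c: min(c)):
            yield sorted(c)


def _partition_calls(calls: list[_Call], params: MergeParams, require_gt: bool):
    """Group by the hard keys, split into components, optimize each."""
    keys: dict[tuple, list[_Call]] = {}
    for c in calls:
        key = (c.chrom,
               c.gt if require_gt else None,
               c.sv_type if params.require_type else None,
               c.strands if params.require_strand else None)
        keys.setdefault(key, []).append(c)
    clusters: list[list[_Call]] = []
    for key in sorted(keys, key=repr):
        group = keys[key]
        for comp_idx in _components(group, params, require_gt):
            comp = [group[i] for i in comp_idx]
            if len(comp) <= params.exact_component_limit:
                part = _optimal_partition(comp, params, require_gt)
            else:
                part = _greedy_partition(comp, params, require_gt)
            for cl in part:
                clusters.append([comp[i] for i in cl])
    return clusters


def _representative(members: list[_Call]) -> tuple[int, int | None]:
    pos = median_low(sorted(m.pos for m in members))
    ends = [m.end for m in members if m.end is not None]
    end = median_low(sorted(ends)) if ends else None
    return pos, end


def _calls_from_records(callsets: list[list[VariantRecord]], params: MergeParams) -> list[_Call]:
    calls = []
    idx = 0
    for k, records in enumerate(callsets):
        for r in records:
            if r.sv_type == "SNP":
                continue
            if r.length is not None and r.length < params.min_len:
                continue
            sample, gt = next(iter(r.genotypes.items()))
            calls.append(_Call(
                idx=idx, chrom=r.chrom, pos=r.pos, end=r.end, sv_type=r.sv_type,
                strands=r.strands, gt=gt, owner=r.caller or f"caller{k}",
                call_id=r.variant_id or f"c{k}_{idx}", length=r.length, payload=r,
            ))
            idx += 1
    return calls


def merge_per_sample(callsets: list[list[VariantRecord]], params: MergeParams | None = None,
                     sample: str | None = None) -> list[ConsensusSV]:
    """Consensus calls for one sample from its per-caller call sets.

    Calls shorter than ``min_len`` are excluded.  When two retained clusters
    from different genotype partitions fall within ``max_dist`` at one locus
    (possible under jitter), the cluster with more supporting callers wins,
    then the one with the smaller coordinate.
    """
    params = params or MergeParams()
    calls = _calls_from_records(callsets, params)
    if sample is None:
        for c in calls:
            sample = next(iter(c.payload.genotypes))
            break
    clusters = _partition_calls(calls, params, params.require_genotype_agreement)
    out: list[ConsensusSV] = []
    for members in clusters:
        if len(members) < params.min_support:
            continue
        pos, end = _representative(members)
        lengths = [m.length for m in members if m.length is not None]
        m0 = members[0]
        out.append(ConsensusSV(
            chrom=m0.chrom, pos=pos, end=end,
            length=median_low(sorted(lengths)) if lengths else None,
            sv_type=m0.sv_type, strands=m0.strands,
            genotypes={sample: m0.gt},
            support={sample: frozenset(m.owner for m in members)},
            member_ids=tuple(m.call_id for m in members),
        ))
    out = _resolve_genotype_conflicts(out, params, sample)
    out.sort(key=lambda c: (c.chrom, c.pos))
    for i, c in enumerate(out):
        c.variant_id = f"{sample}_cons{i}"
    return out


def _resolve_genotype_conflicts(consensus: list[ConsensusSV], params: MergeParams,
                                sample: str) -> list[ConsensusSV]:
    """Keep one consensus call where genotype partitions collide at a locus."""
    by_key: dict[tuple, list[ConsensusSV]] = {}
    for c in consensus:
        by_key.setdefault((c.chrom, c.sv_type, c.strands), []).append(c)
    kept: list[ConsensusSV] = []
    for group in by_key.values():
        group.sort(key=lambda c: (-len(c.support.get(sample, ())), c.pos))
        chosen: list[ConsensusSV] = []
        for c in group:
            near = any(
                abs(c.pos - k.pos) <= params.max_dist
                and (c.end is None or k.end is None or abs(c.end - k.end) <= params.max_dist)
                for k in chosen
            )
            if not near:
                chosen.append(c)
        kept.extend(chosen)
    return kept


def merge_across_samples(per_sample: dict[str, list[ConsensusSV]],
                         params: MergeParams | None = None,
                         absent_genotype: int = 0) -> list[ConsensusSV]:
    """Merge per-sample consensus calls into one cohort callset.

    Genotype agreement is not required across samples; every cluster becomes
    one cohort SV typed in all samples, with samples lacking a member call
    set to ``absent_genotype`` (0 = reference by convention; pass
    ``vcfio.MISSING`` for missing instead).
    """
    params = (params or MergeParams()).cross_sample()
    calls: list[_Call] = []
    idx = 0
    for sample in sorted(per_sample):
        for c in per_sample[sample]:
            calls.append(_Call(
                idx=idx, chrom=c.chrom, pos=c.pos, end=c.end, sv_type=c.sv_type,
                strands=c.strands, gt=c.genotypes.get(sample, MISSING), owner=sample,
                call_id=c.variant_id or f"{sample}_{idx}", length=c.length, payload=c,
            ))
            idx += 1
    clusters = _partition_calls(calls, params, require_gt=False)
    all_samples = sorted(per_sample)
    out: list[ConsensusSV] = []
    for members in clusters:
        if len(members) < params.min_support:
            continue
        pos, end = _representative(members)
        lengths = [m.length for m in members if m.length is not None]
        m0 = members[0]
        gts = {s: absent_genotype for s in all_samples}
        support: dict[str, frozenset[str]] = {}
        for m in members:
            gts[m.owner] = m.gt
            support[m.owner] = m.payload.support.get(m.owner, frozenset())
        out.append(ConsensusSV(
            chrom=m0.chrom, pos=pos, end=end,
            length=median_low(sorted(lengths)) if lengths else None,
            sv_type=m0.sv_type, strands=m0.strands, genotypes=gts, support=support,
            member_ids=tuple(m.call_id for m in members),
        ))
    out.sort(key=lambda c: (c.chrom, c.pos))
    for i, c in enumerate(out):
        c.variant_id = f"cohort_sv{i}"
    return out


def _all_partitions(items: list[int]):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_merge_oracle(callsets: list[list[VariantRecord]],
                             params: MergeParams | None = None,
                             sample: str | None = None) -> list[ConsensusSV]:
    """Exhaustive reference merge for <= 10 calls (per-sample contract).

    Enumerates every partition of the calls, discards partitions containing a
    pairwise-incompatible cluster, and selects the best under the same
    objective as the fast merge.  Independent of the fast path: no component
    decomposition, no pruned generation.
    """
    params = params or MergeParams()
    calls = _calls_from_records(callsets, params)
    if len(calls) > 10:
        raise ValueError("oracle refuses more than 10 calls")
    if sample is None and calls:
        sample = next(iter(calls[0].payload.genotypes))
    require_gt = params.require_genotype_agreement
    n = len(calls)
    best = None
    best_part: list[list[int]] = []
    for part in _all_partitions(list(range(n))):
        ok = True
        for cl in part:
            for i, j in itertools.combinations(cl, 2):
                if not _compatible(calls[i], calls[j], params, require_gt):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        s = _score([tuple(c) for c in part], calls, params)
        if best is None or s < best:
            best, best_part = s, part
    out: list[ConsensusSV] = []
    for cl in best_part:
        if len(cl) < params.min_support:
            continue
        members = [calls[i] for i in sorted(cl)]
        pos, end = _representative(members)
        lengths = [m.length for m in members if m.length is not None]
        m0 = members[0]
        out.append(ConsensusSV(
            chrom=m0.chrom, pos=pos, end=end,
            length=median_low(sorted(lengths)) if lengths else None,
            sv_type=m0.sv_type, strands=m0.strands,
            genotypes={sample: m0.gt},
            support={sample: frozenset(m.owner for m in members)},
            member_ids=tuple(m.call_id for m in members),
        ))
    out = _resolve_genotype_conflicts(out, params, sample or "sample")
    out.sort(key=lambda c: (c.chrom, c.pos))
    return out
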