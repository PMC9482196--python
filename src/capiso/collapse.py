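"""Three-stage reduction of filtered reads to a non-redundant isoform set.

Stage 1 (`collapse_sample`) collapses reads within one sample: reads are
grouped by *identical* junction chain, and within a group terminal 5'/3' ends
are clustered under small wobble tolerances (default 100/100 bp). Junction
coordinates are never wobbled — CCS-polished and simulated junctions are
exact — which makes the procedure order-independent. A chain that is a strict
3'-anchored suffix of a longer chain is a distinct group and is never merged
into the longer model (the "don't merge 5'-shorter" rule): 5'-truncated
molecules must not inflate full-length models.

Stage 2 (`merge_samples`) combines samples: only models supported by at least
`min_fl_for_merge` (default 50) full-length reads *within one sample* enter;
models with identical junction chains whose ends agree within the stage-1
wobbles are unified, keeping per-sample counts side by side.

Stage 3 (`merge_internal_junctions`) merges on internal junctions only, with
wide end variability (defaults 300 bp at 5', 2000 bp at 3'): models with
identical junction chains are unified when their ends fall within those
tolerances of the representative, which is the model whose best-supporting
sample has the best library rank (libraries ranked by their count of
polyadenylated on-target reads). The representative also donates the reported
terminal ends.

End clustering uses representative-bounded connected components: the
representative is fixed first (by support, then extremity, then rank), and
membership is re-checked against the representative rather than chained
pairwise, so tolerance drift is bounded and the partition is deterministic.
All stages are idempotent and never increase the model count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .locus import ExonChain, LongReadRecord, TranscriptModel

#: sample name -> rank (1 = best)
LibraryRank = dict[str, int]


@dataclass
class CollapseConfig:
    wobble5_stage1: int = 100
    wobble3_stage1: int = 100
    no_merge_5_shorter: bool = True
    min_fl_for_merge: int = 50
    tol5_stage3: int = 300
    tol3_stage3: int = 2000

    def __post_init__(self) -> None:
        for name in ("wobble5_stage1", "wobble3_stage1", "min_fl_for_merge",
                     "tol5_stage3", "tol3_stage3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def rank_libraries(polya_read_counts: dict[str, int]) -> LibraryRank:
    """Rank libraries by polyadenylated on-target read count, descending.

    Ties are broken by sample name; rank 1 is best.
    """
    ordered = sorted(polya_read_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {sample: i + 1 for i, (sample, _) in enumerate(ordered)}


def rank_from_reads(reads: list[LongReadRecord]) -> LibraryRank:
    counts: Counter = Counter(r.sample for r in reads)
    return rank_libraries(dict(counts))


# ---------------------------------------------------------------------------
# end clustering
# ---------------------------------------------------------------------------

def _extremity_keys(strand: str):
    """Sort keys making the most 5'-extreme / 3'-extreme end sort first."""
    if strand == "+":
        return (lambda t5: t5), (lambda t3: -t3)
    return (lambda t5: -t5), (lambda t3: t3)


def _modal_end(values: list[int], extreme_key) -> int:
    """The end supported by most values; ties broken by transcript extremity."""
    counts = Counter(values)
    return min(counts, key=lambda v: (-counts[v], extreme_key(v)))


def _cluster_ends(
    items: list,
    get_ends,
    weight,
    wobble5: int,
    wobble3: int,
    strand: str,
    seed_order_key=None,
) -> list[list]:
    """Partition items by terminal ends under representative-bounded wobble.

    The seed of each cluster is the remaining item whose (5', 3') end pair has
    the highest total weight (ties: transcript extremity, then
    `seed_order_key`); members are all remaining items within wobble of the
    seed's ends. The seed is always a member, so the loop terminates.
    """
    key5, key3 = _extremity_keys(strand)
    remaining = list(items)
    clusters = []
    while remaining:
        pair_weight: Counter = Counter()
        for it in remaining:
            pair_weight[get_ends(it)] += weight(it)

        def seed_key(it):
            t5, t3 = get_ends(it)
            extra = seed_order_key(it) if seed_order_key else 0
            return (-pair_weight[(t5, t3)], key5(t5), key3(t3), extra)

        seed = min(remaining, key=seed_key)
        s5, s3 = get_ends(seed)
        members = [
            it
            for it in remaining
            if abs(get_ends(it)[0] - s5) <= wobble5
            and abs(get_ends(it)[1] - s3) <= wobble3
        ]
        member_set = {id(m) for m in members}
        remaining = [it for it in remaining if id(it) not in member_set]
        clusters.append((seed, members))
    return clusters


# ---------------------------------------------------------------------------
# stage 1: within-sample collapse
# ---------------------------------------------------------------------------

def collapse_sample(
    reads: list[LongReadRecord], cfg: CollapseConfig
) -> list[TranscriptModel]:
    """Collapse one sample's multi-exon reads into transcript models."""
    if not reads:
        return []
    sample = reads[0].sample
    strands = {r.chain.strand for r in reads}
    if len(strands) > 1:
        raise ValueError(f"mixed strands in sample {sample!r}: {sorted(strands)}")
    if any(r.sample != sample for r in reads):
        raise ValueError("collapse_sample expects reads from a single sample")
    if any(r.chain.is_mono_exon for r in reads):
        raise ValueError("collapse_sample expects multi-exon reads (filter first)")
    strand = strands.pop()
    key5, key3 = _extremity_keys(strand)

    groups: dict[tuple, list[LongReadRecord]] = {}
    for r in reads:
        groups.setdefault(r.chain.chain_key(), []).append(r)

    models = []
    for key in sorted(groups, key=_chain_sort_key):
        group = groups[key]
        clusters = _cluster_ends(
            group,
            get_ends=lambda r: (r.chain.tss(), r.chain.tes()),
            weight=lambda r: 1,
            wobble5=cfg.wobble5_stage1,
            wobble3=cfg.wobble3_stage1,
            strand=strand,
            seed_order_key=lambda r: r.read_id,
        )
        for _, members in clusters:
            rep5 = _modal_end([m.chain.tss() for m in members], key5)
            rep3 = _modal_end([m.chain.tes() for m in members], key3)
            chain = members[0].chain.with_ends(rep5, rep3)
            models.append(
                TranscriptModel(
                    id="",
                    chain=chain,
                    counts={sample: len(members)},
                    members=tuple(sorted(m.read_id for m in members)),
                )
            )
    models.sort(key=lambda m: (m.chain.start, m.chain.end, m.junction_chain()))
    for i, m in enumerate(models, start=1):
        m.id = f"{sample}.{i}"
    return models


def _chain_sort_key(chain_key: tuple) -> tuple:
    chrom, strand, junctions = chain_key
    return (chrom, strand, len(junctions), junctions)


def _best_sample(model: TranscriptModel) -> str:
    return min(model.counts, key=lambda s: (-model.counts[s], s))


def _merge_cluster(seed: TranscriptModel, members: list[TranscriptModel],
                   new_id: str) -> TranscriptModel:
    counts: Counter = Counter()
    member_ids: list[str] = []
    for m in members:
        counts.update(m.counts)
        member_ids.append(m.id)
    return TranscriptModel(
        id=new_id,
        chain=seed.chain,
        counts=dict(counts),
        members=tuple(sorted(member_ids)),
        rank_key=seed.rank_key,
    )


# ---------------------------------------------------------------------------
# stage 2: cross-sample merge of well-supported models
# ---------------------------------------------------------------------------

def merge_samples(
    models_by_sample: dict[str, list[TranscriptModel]], cfg: CollapseConfig
) -> list[TranscriptModel]:
    """Merge per-sample models supported by >= `min_fl_for_merge` reads.

    A model qualifies through its support within its own sample; identical
    junction chains across samples are unified when their ends agree within
    the stage-1 wobbles, with per-sample counts retained side by side.
    """
    eligible = []
    for sample in sorted(models_by_sample):
        for m in models_by_sample[sample]:
            if m.counts.get(sample, 0) >= cfg.min_fl_for_merge:
                eligible.append(m)

    groups: dict[tuple, list[TranscriptModel]] = {}
    for m in eligible:
        groups.setdefault(m.chain.chain_key(), []).append(m)

    merged = []
    for key in sorted(groups, key=_chain_sort_key):
        group = groups[key]
        strand = key[1]
        clusters = _cluster_ends(
            group,
            get_ends=lambda m: (m.tss(), m.tes()),
            weight=lambda m: m.total_count,
            wobble5=cfg.wobble5_stage1,
            wobble3=cfg.wobble3_stage1,
            strand=strand,
            seed_order_key=lambda m: m.id,
        )
        for seed, members in clusters:
            merged.append(_merge_cluster(seed, members, new_id=""))
    merged.sort(key=lambda m: (m.chain.start, m.chain.end, m.junction_chain()))
    for i, m in enumerate(merged, start=1):
        m.id = f"M{i}"
    return merged


# ---------------------------------------------------------------------------
# stage 3: internal-junction-only merge with wide end variability
# ---------------------------------------------------------------------------

def merge_internal_junctions(
    models: list[TranscriptModel],
    cfg: CollapseConfig,
    rank: LibraryRank | None = None,
) -> list[TranscriptModel]:
    """Unify models with identical junction chains under wide end tolerances.

    The surviving representative (which donates the reported ends) is the
    model whose best-supporting sample has the best library rank, then the
    highest read count, then lexicographic id. Chains that differ in any
    internal junction — including strict 3'-anchored suffixes — are never
    merged.
    """
    rank = rank or {}
    groups: dict[tuple, list[TranscriptModel]] = {}
    for m in models:
        groups.setdefault(m.chain.chain_key(), []).append(m)

    def rep_priority(m: TranscriptModel) -> tuple:
        best = _best_sample(m) if m.counts else ""
        return (rank.get(best, len(rank) + 1), -m.total_count, m.id)

    merged = []
    for key in sorted(groups, key=_chain_sort_key):
        remaining = sorted(groups[key], key=rep_priority)
        while remaining:
            seed = remaining[0]
            s5, s3 = seed.tss(), seed.tes()
            members = [
                m
                for m in remaining
                if abs(m.tss() - s5) <= cfg.tol5_stage3
                and abs(m.tes() - s3) <= cfg.tol3_stage3
            ]
            member_ids = {id(m) for m in members}
            remaining = [m for m in remaining if id(m) not in member_ids]
            merged.append(_merge_cluster(seed, members, new_id=""))
    merged.sort(key=lambda m: (m.chain.start, m.chain.end, m.junction_chain()))
    for i, m in enumerate(merged, start=1):
        m.id = f"ISO{i:03d}"
    return merged
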