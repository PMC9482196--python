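"""Read-level and alignment-level filters producing the analysis read set.

Three filters turn raw clustered long reads into on-target, antisense,
multi-exon full-length reads:

* cluster quality — subreads >= 2, cluster quality >= 0.99, polyA tail >= 20 bp
  (all inclusive, "at least" thresholds);
* alignment — primary alignment fully inside the target window, MAPQ strictly
  above 20, strictly fewer than 50 clipped bases;
* structure — at least two exons, on the configured target strand (the target
  lncRNA is antisense, so reads on the opposite strand are sense
  contamination).

The filters are pure predicates and commute; `apply_filters` additionally
attributes each dropped read to its first failing filter, in the order above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .locus import GenomicInterval, LongReadRecord


@dataclass
class FilterConfig:
    min_subreads: int = 2
    min_quality: float = 0.99
    min_polya: int = 20
    min_mapq_exclusive: int = 20
    max_clipped_exclusive: int = 50
    target_region: GenomicInterval | None = None
    target_strand: str = "-"
    drop_mono_exon: bool = True
    drop_opposite_strand: bool = True

    def __post_init__(self) -> None:
        for name in ("min_subreads", "min_polya", "min_mapq_exclusive",
                     "max_clipped_exclusive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.min_quality <= 1.0):
            raise ValueError("min_quality must be in [0, 1]")


def _require(read: LongReadRecord, attr: str):
    value = getattr(read, attr, None)
    if value is None:
        raise ValueError(f"read {read.read_id!r}: missing metadata field {attr!r}")
    return value


def passes_cluster_quality(read: LongReadRecord, cfg: FilterConfig) -> bool:
    return (
        _require(read, "subreads") >= cfg.min_subreads
        and _require(read, "quality") >= cfg.min_quality
        and _require(read, "polya_len") >= cfg.min_polya
    )


def passes_alignment(read: LongReadRecord, cfg: FilterConfig) -> bool:
    if not read.is_primary:
        return False
    if read.mapq <= cfg.min_mapq_exclusive:
        return False
    if read.clipped >= cfg.max_clipped_exclusive:
        return False
    if cfg.target_region is not None and not cfg.target_region.contains(
        read.chain.chrom, read.chain.start, read.chain.end
    ):
        return False
    return True


def passes_structure(read: LongReadRecord, cfg: FilterConfig) -> bool:
    if cfg.drop_mono_exon and read.chain.is_mono_exon:
        return False
    if cfg.drop_opposite_strand and read.chain.strand != cfg.target_strand:
        return False
    return True


def filter_cluster_quality(
    reads: list[LongReadRecord], cfg: FilterConfig
) -> list[LongReadRecord]:
    """Keep reads with subreads >= 2, quality >= 0.99 and polyA >= 20 bp."""
    return [r for r in reads if passes_cluster_quality(r, cfg)]


def filter_alignment(
    reads: list[LongReadRecord], cfg: FilterConfig
) -> list[LongReadRecord]:
    """Keep primary, on-target reads with MAPQ > 20 and < 50 clipped bases."""
    return [r for r in reads if passes_alignment(r, cfg)]


def filter_structure(
    reads: list[LongReadRecord], cfg: FilterConfig
) -> list[LongReadRecord]:
    """Drop single-exon reads and reads on the non-target (sense) strand."""
    return [r for r in reads if passes_structure(r, cfg)]


_PREDICATES = (
    ("cluster_quality", passes_cluster_quality),
    ("alignment", passes_alignment),
    ("structure", passes_structure),
)


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    dropped_by_reason: dict[str, int] = field(default_factory=dict)
    dropped_reads: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "dropped_by_reason": dict(self.dropped_by_reason),
        }


def apply_filters(
    reads: list[LongReadRecord], cfg: FilterConfig
) -> tuple[list[LongReadRecord], FilterReport]:
    """Apply all three filters; attribute drops to the first failing filter."""
    report = FilterReport(n_input=len(reads))
    report.dropped_by_reason = {name: 0 for name, _ in _PREDICATES}
    kept = []
    for read in reads:
        for name, pred in _PREDICATES:
            if not pred(read, cfg):
                report.dropped_by_reason[name] += 1
                report.dropped_reads.append((read.read_id, name))
                break
        else:
            kept.append(read)
    report.n_kept = len(kept)
    return kept, report
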