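"""Read-to-isoform assignment, the counts matrix, and usage statistics.

Reads count for an isoform only as full splice matches: the read's junction
chain must equal the isoform's exactly, terminal ends free. The counts matrix
(isoform x sample, time-course sample order) feeds the high-confidence filter
(> 100 cumulative reads and detection in >= 2 samples), per-sample isoform
proportions, start-exon usage (with the > 500 cumulative-read reporting
cutoff), alternative acceptor-site usage within a chosen exon, 3'-end /
polyA-class usage on the terminal exon, and the junction sample-prevalence
statistic (samples with >= 10 junction-spanning reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .locus import Junction, LongReadRecord, TranscriptModel


@dataclass
class QuantConfig:
    min_reads_exclusive: int = 100
    min_samples: int = 2
    min_start_exon_reads: int = 500
    junction_prevalence_min_reads: int = 10
    prevalence_strict: bool = False  # False: >= threshold; True: > threshold
    ism_rescue: bool = False  # also count reads that are 3'-anchored sub-chains
    usage_high_confidence_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_reads_exclusive", "min_samples", "min_start_exon_reads",
                     "junction_prevalence_min_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FeatureAnnotation:
    """Named locus features used by the usage statistics.

    `start_exons` maps a start-exon name to its genomic (start, end) window;
    `acceptors` maps an acceptor-site name to the genomic acceptor position of
    the junction entering the exon of interest; `polya_classes` maps a 3'-end
    class name to the genomic position of its polyA site on the terminal exon.
    """

    chrom: str
    strand: str
    start_exons: dict[str, tuple[int, int]] = field(default_factory=dict)
    acceptors: dict[str, int] = field(default_factory=dict)
    polya_classes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ivs = sorted(self.start_exons.values())
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("start-exon intervals overlap")

    def start_exon_of(self, tss: int) -> str | None:
        # last transcribed base of the 5' end, so a '-' TSS (exclusive bound)
        # falls inside its own exon window
        pos = tss if self.strand == "+" else tss - 1
        for name, (s, e) in self.start_exons.items():
            if s <= pos < e:
                return name
        return None

    def to_yaml(self, path) -> None:
        data = {
            "chrom": self.chrom,
            "strand": self.strand,
            "start_exons": {k: list(v) for k, v in self.start_exons.items()},
            "acceptors": dict(self.acceptors),
            "polya_classes": dict(self.polya_classes),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureAnnotation":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            chrom=data["chrom"],
            strand=data["strand"],
            start_exons={k: tuple(v) for k, v in data["start_exons"].items()},
            acceptors={k: int(v) for k, v in data.get("acceptors", {}).items()},
            polya_classes={
                k: int(v) for k, v in data.get("polya_classes", {}).items()
            },
        )


# ---------------------------------------------------------------------------
# counts matrix
# ---------------------------------------------------------------------------

def assign_reads(
    reads: list[LongReadRecord],
    models: list[TranscriptModel],
    samples: list[str] | None = None,
    ism_rescue: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Count full-splice-match reads per isoform and sample.

    A read counts for an isoform iff its junction chain equals the isoform's
    (terminal ends free). If several isoforms share a chain, the tie is broken
    by nearest 3' end, then nearest 5' end. Mono-exon reads and reads matching
    no model are tallied as unassigned. Returns (counts matrix, unassigned
    reads per sample).
    """
    if samples is None:
        samples = sorted({r.sample for r in reads})
    by_chain: dict[tuple, list[TranscriptModel]] = {}
    for m in models:
        by_chain.setdefault(m.chain.chain_key(), []).append(m)
    suffix_index = _build_suffix_index(models) if ism_rescue else None

    ids = [m.id for m in models]
    counts = pd.DataFrame(0, index=ids, columns=samples, dtype=int)
    unassigned = pd.Series(0, index=samples, dtype=int)
    for r in reads:
        target = None
        if not r.chain.is_mono_exon:
            cands = by_chain.get(r.chain.chain_key())
            if not cands and suffix_index is not None:
                cands = suffix_index.get(r.chain.junction_chain())
            if cands:
                target = min(
                    cands,
                    key=lambda m: (
                        abs(m.tes() - r.chain.tes()),
                        abs(m.tss() - r.chain.tss()),
                        m.id,
                    ),
                )
        if target is None:
            unassigned[r.sample] += 1
        else:
            counts.loc[target.id, r.sample] += 1
    return counts, unassigned


def _build_suffix_index(models) -> dict[tuple, list[TranscriptModel]]:
    index: dict[tuple, list[TranscriptModel]] = {}
    for m in models:
        jc = m.chain.junction_chain()
        for k in range(1, len(jc)):
            index.setdefault(jc[k:], []).append(m)
    return index


def high_confidence_filter(counts: pd.DataFrame, cfg: QuantConfig) -> list[str]:
    """Isoforms with > `min_reads_exclusive` total reads in >= `min_samples`
    samples with any support."""
    totals = counts.sum(axis=1)
    n_detected = (counts > 0).sum(axis=1)
    keep = (totals > cfg.min_reads_exclusive) & (n_detected >= cfg.min_samples)
    return list(counts.index[keep])


def isoform_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample isoform proportions; all-zero samples become all-NaN."""
    totals = counts.sum(axis=0)
    props = counts.div(totals.where(totals > 0), axis=1)
    return props


# ---------------------------------------------------------------------------
# usage statistics
# ---------------------------------------------------------------------------

@dataclass
class StartExonUsage:
    totals: pd.DataFrame  # start exon x sample read totals
    proportions: pd.DataFrame
    reported: list[str]  # start exons with cumulative reads > cutoff


def start_exon_usage(
    models: list[TranscriptModel],
    counts: pd.DataFrame,
    annotation: FeatureAnnotation,
    cfg: QuantConfig,
) -> StartExonUsage:
    """Per-sample read totals and proportions grouped by named start exon.

    Models whose TSS falls in no named window go to the "other" bucket;
    exons with cumulative reads > `min_start_exon_reads` are "reported".
    """
    by_id = {m.id: m for m in models}
    names = list(annotation.start_exons) + ["other"]
    totals = pd.DataFrame(0, index=names, columns=counts.columns, dtype=int)
    for iso_id in counts.index:
        model = by_id[iso_id]
        name = annotation.start_exon_of(model.tss()) or "other"
        totals.loc[name] += counts.loc[iso_id]
    props = _bucket_proportions(totals)
    cumulative = totals.sum(axis=1)
    reported = [
        n for n in annotation.start_exons if cumulative[n] > cfg.min_start_exon_reads
    ]
    return StartExonUsage(totals=totals, proportions=props, reported=reported)


def acceptor_site_usage(
    models: list[TranscriptModel],
    counts: pd.DataFrame,
    annotation: FeatureAnnotation,
) -> pd.DataFrame:
    """Per-sample proportions over named alternative acceptor sites.

    Each isoform votes for the named acceptor its junction chain uses (at most
    one of the alternatives can appear in a chain); isoforms using none go to
    "other". Requires a non-empty named-acceptor map.
    """
    if not annotation.acceptors:
        raise ValueError("annotation defines no named acceptor sites")
    by_id = {m.id: m for m in models}
    pos_to_name = {pos: name for name, pos in annotation.acceptors.items()}
    names = list(annotation.acceptors) + ["other"]
    totals = pd.DataFrame(0, index=names, columns=counts.columns, dtype=int)
    for iso_id in counts.index:
        chain = by_id[iso_id].chain
        bucket = "other"
        for s, e in chain.junction_chain():
            acceptor_pos = s if chain.strand == "-" else e
            if acceptor_pos in pos_to_name:
                bucket = pos_to_name[acceptor_pos]
                break
        totals.loc[bucket] += counts.loc[iso_id]
    return _bucket_proportions(totals)


def end_class_usage(
    models: list[TranscriptModel],
    counts: pd.DataFrame,
    annotation: FeatureAnnotation,
    upstream_slack: int = 100,
) -> pd.DataFrame:
    """Per-sample proportions over named polyA-site (3'-end length) classes.

    Each isoform's 3' end is binned to the nearest class position; ends lying
    transcript-upstream of every class by more than `upstream_slack` bp go to
    "other".
    """
    if not annotation.polya_classes:
        raise ValueError("annotation defines no polyA-site classes")
    by_id = {m.id: m for m in models}
    sign = 1 if annotation.strand == "+" else -1
    # transcript-axis coordinate: increases in the direction of transcription
    taxis = {name: sign * pos for name, pos in annotation.polya_classes.items()}
    first = min(taxis.values())
    names = list(annotation.polya_classes) + ["other"]
    totals = pd.DataFrame(0, index=names, columns=counts.columns, dtype=int)
    for iso_id in counts.index:
        t = sign * by_id[iso_id].tes()
        if t < first - upstream_slack:
            bucket = "other"
        else:
            bucket = min(taxis, key=lambda n: (abs(t - taxis[n]), taxis[n]))
        totals.loc[bucket] += counts.loc[iso_id]
    return _bucket_proportions(totals)


def _bucket_proportions(totals: pd.DataFrame) -> pd.DataFrame:
    sums = totals.sum(axis=0)
    return totals.div(sums.where(sums > 0), axis=1)


def junction_prevalence(
    table: pd.DataFrame,
    cfg: QuantConfig,
    junctions: list | None = None,
) -> pd.Series:
    """Samples passing the junction-spanning-read threshold, per junction.

    `table` has columns (sample_id, junction, count). Default keeps samples
    with count >= threshold; `prevalence_strict` switches to a strict >.
    """
    required = {"sample_id", "junction", "count"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    thr = cfg.junction_prevalence_min_reads
    mask = table["count"] > thr if cfg.prevalence_strict else table["count"] >= thr
    passing = table[mask].groupby("junction")["sample_id"].nunique()
    if junctions is None:
        junctions = sorted(table["junction"].unique())
    return pd.Series(
        [int(passing.get(j, 0)) for j in junctions], index=junctions, dtype=int
    )


def junction_count_table(reads: list[LongReadRecord]) -> pd.DataFrame:
    """Per-sample junction-spanning read counts from a read set."""
    rows: dict[tuple, int] = {}
    for r in reads:
        for j in r.chain.junction_chain():
            key = (r.sample, j)
            rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [(s, j, n) for (s, j), n in sorted(rows.items())],
        columns=["sample_id", "junction", "count"],
    )
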