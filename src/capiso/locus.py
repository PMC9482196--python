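"""Core genomic data model: intervals, exon chains, junction chains, transcripts.

All coordinates are 0-based half-open (BED convention) throughout the package;
format readers/writers convert at the boundary. A transcript on the minus
strand has its 5' end (TSS) at the *higher* genomic coordinate: the target
lncRNA is antisense, and every 5'/3' tolerance in the pipeline is applied in
transcript orientation, never in raw genomic orientation.

A *junction chain* is the ordered list of intron (donor, acceptor boundary)
coordinate pairs of a transcript, listed 5'->3' in transcript orientation.
Identity of this chain defines a splice isoform independently of where the
terminal exons start or end, and it is the unit of collapse, merge, FSM read
assignment, and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-")

#: A junction is the genomic (start, end) of an intron, half-open.
Junction = tuple[int, int]
#: Junctions in transcript 5'->3' order.
JunctionChain = tuple[Junction, ...]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """Whether [start, end) on `chrom` lies fully inside this interval."""
        return chrom == self.chrom and start >= self.start and end <= self.end


@dataclass(frozen=True)
class ExonChain:
    """A stranded, ordered, disjoint set of exons on one sequence.

    Exons are stored in ascending genomic order regardless of strand; strand
    determines transcript orientation for TSS/TES and junction-chain order.
    """

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if len(exons) < 1:
            raise ValueError("exon chain requires at least one exon")
        prev_end = None
        for s, e in exons:
            if s < 0 or s >= e:
                raise ValueError(f"invalid exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"exons not sorted/disjoint: ({s}, {e}) after end {prev_end}"
                )
            prev_end = e

    # -- basic geometry ----------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_mono_exon(self) -> bool:
        return len(self.exons) == 1

    def introns(self) -> tuple[Junction, ...]:
        """Introns as (start, end) pairs in ascending genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"non-positive intron between {e1} and {s2}")
            out.append((e1, s2))
        return tuple(out)

    def junction_chain(self) -> JunctionChain:
        """Introns in transcript 5'->3' order (reversed on the minus strand)."""
        ivs = self.introns()
        return tuple(reversed(ivs)) if self.strand == "-" else ivs

    # -- transcript orientation --------------------------------------------

    def tss(self) -> int:
        """Genomic coordinate of the transcript 5' end.

        On '+' this is the genomic start; on '-' it is the (exclusive)
        genomic end of the last exon.
        """
        return self.start if self.strand == "+" else self.end

    def tes(self) -> int:
        """Genomic coordinate of the transcript 3' end (opposite of tss)."""
        return self.end if self.strand == "+" else self.start

    def with_ends(self, tss: int, tes: int) -> "ExonChain":
        """Return a copy with terminal exon outer boundaries replaced.

        `tss`/`tes` are in the same convention as :meth:`tss`/:meth:`tes`.
        Internal junctions are untouched; the new ends must not cross the
        first/last junction.
        """
        exons = list(self.exons)
        if self.strand == "+":
            exons[0] = (tss, exons[0][1])
            exons[-1] = (exons[-1][0], tes)
        else:
            exons[-1] = (exons[-1][0], tss)
            exons[0] = (tes, exons[0][1])
        return ExonChain(self.chrom, self.strand, tuple(exons))

    def chain_key(self) -> tuple:
        """Hashable identity of the splice structure (chrom, strand, junctions)."""
        return (self.chrom, self.strand, self.junction_chain())


def junctions_of(chain: ExonChain) -> JunctionChain:
    """Junction chain of `chain` in transcript 5'->3' order.

    For n exons, returns n-1 junctions; on the minus strand the first
    returned junction is the one nearest the genomic end (transcript 5').
    Mono-exonic chains yield an empty tuple.
    """
    return chain.junction_chain()


@dataclass
class TranscriptModel:
    """A transcript model: exon chain plus identity and support metadata.

    ``counts`` maps sample name -> full-length read support; ``members``
    records provenance (ids of reads/models merged into this one);
    ``rank_key`` carries library-ranking support where relevant.
    """

    id: str
    chain: ExonChain
    counts: dict[str, int] = field(default_factory=dict)
    members: tuple[str, ...] = ()
    rank_key: float = 0.0

    def __post_init__(self) -> None:
        for sample, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for sample {sample!r} in {self.id}")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def tss(self) -> int:
        return self.chain.tss()

    def tes(self) -> int:
        return self.chain.tes()

    def junction_chain(self) -> JunctionChain:
        return self.chain.junction_chain()


@dataclass
class LongReadRecord:
    """One aligned full-length read: exon chain plus CCS/alignment metadata."""

    read_id: str
    sample: str
    chain: ExonChain
    subreads: int = 1
    quality: float = 1.0
    polya_len: int = 0
    mapq: int = 60
    clipped: int = 0
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.subreads < 1:
            raise ValueError(f"{self.read_id}: subreads must be >= 1")
        if not (0.0 <= self.quality <= 1.0):
            raise ValueError(f"{self.read_id}: quality outside [0, 1]")
        if self.polya_len < 0 or self.mapq < 0 or self.clipped < 0:
            raise ValueError(f"{self.read_id}: negative metadata field")
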