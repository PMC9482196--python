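"""Reference-relative transcript classification and end annotation.

Categories, relative to a reference catalog:

* FSM (full splice match) — the junction chain is identical to a reference's;
  terminal 5'/3' ends may differ by any amount.
* ISM (incomplete splice match) — the chain is a strict, contiguous,
  3'-anchored sub-chain of a reference's (fewer 5' exons, internal junctions
  perfectly consistent). A config switch widens this to any contiguous
  sub-chain for comparability with generic classifiers.
* NIC (novel in catalog) — every donor and acceptor site is known to the
  catalog but the combination is novel.
* NNC (novel not in catalog) — at least one donor or acceptor site is absent
  from the catalog.

Every multi-exon model receives exactly one category. The module also
annotates splice-site dinucleotides (canonical set GT-AG, GC-AG, AT-AC, read
on the transcript strand), signed distance from the TSS to the nearest CAGE
peak summit, and polyA signal motifs in a window upstream of the 3' end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from . import io as cio
from .locus import Junction, TranscriptModel

CATEGORIES = ("FSM", "ISM", "NIC", "NNC")
CANONICAL_PAIRS = frozenset({"GT-AG", "GC-AG", "AT-AC"})

#: donor/acceptor site identity: (chrom, strand, position)
Site = tuple[str, str, int]


def donor_acceptor(chrom: str, strand: str, junction: Junction) -> tuple[Site, Site]:
    """Donor and acceptor site of an intron, in transcript orientation.

    For intron [s, e): on '+' the donor is at s and the acceptor at e; on '-'
    the donor is at e and the acceptor at s.
    """
    s, e = junction
    if strand == "+":
        return (chrom, strand, s), (chrom, strand, e)
    return (chrom, strand, e), (chrom, strand, s)


@dataclass
class ReferenceCatalog:
    """Reference transcript models plus derived donor/acceptor site sets."""

    models: list[TranscriptModel]
    donor_sites: frozenset[Site] = field(init=False)
    acceptor_sites: frozenset[Site] = field(init=False)

    def __post_init__(self) -> None:
        donors, acceptors = set(), set()
        for m in self.models:
            chain = m.chain
            for j in chain.junction_chain():
                d, a = donor_acceptor(chain.chrom, chain.strand, j)
                donors.add(d)
                acceptors.add(a)
        self.donor_sites = frozenset(donors)
        self.acceptor_sites = frozenset(acceptors)

    @classmethod
    def from_gtf(cls, path) -> "ReferenceCatalog":
        return cls(models=cio.read_gtf(path))

    @classmethod
    def from_bed12(cls, path) -> "ReferenceCatalog":
        return cls(models=cio.read_bed12(path))


@dataclass
class ClassificationResult:
    isoform_id: str
    category: str
    matched_reference_id: str | None = None
    all_canonical: bool | None = None
    junction_dinucleotides: list[str] | None = None
    cage_distance_bp: int | None = None
    within_15bp: bool | None = None
    beyond_250bp: bool | None = None
    polya_motif: str | None = None
    polya_motif_distance: int | None = None


def classify_isoform(
    model: TranscriptModel,
    catalog: ReferenceCatalog,
    generic_ism: bool = False,
) -> tuple[str, str | None]:
    """Category of `model` against `catalog`, with the matched reference
    (FSM/ISM only; multiple candidates resolved by nearest TSS, then id)."""
    chain = model.chain
    if chain.is_mono_exon:
        raise ValueError(
            f"{model.id}: mono-exonic models are outside the category space"
        )
    query = chain.junction_chain()

    fsm = [
        r
        for r in catalog.models
        if r.chain.chain_key() == chain.chain_key()
    ]
    if fsm:
        best = min(fsm, key=lambda r: (abs(r.tss() - model.tss()), r.id))
        return "FSM", best.id

    ism = []
    for r in catalog.models:
        if r.chain.chrom != chain.chrom or r.chain.strand != chain.strand:
            continue
        ref = r.chain.junction_chain()
        if len(query) >= len(ref):
            continue
        if generic_ism:
            hit = any(
                ref[i : i + len(query)] == query
                for i in range(len(ref) - len(query) + 1)
            )
        else:
            hit = ref[len(ref) - len(query):] == query
        if hit:
            ism.append(r)
    if ism:
        best = min(ism, key=lambda r: (abs(r.tss() - model.tss()), r.id))
        return "ISM", best.id

    for j in query:
        d, a = donor_acceptor(chain.chrom, chain.strand, j)
        if d not in catalog.donor_sites or a not in catalog.acceptor_sites:
            return "NNC", None
    return "NIC", None


def splice_canonicality(
    model: TranscriptModel, genome: cio.GenomeSource
) -> tuple[list[str], bool]:
    """Per-junction donor-acceptor dinucleotide pairs, on the transcript strand."""
    chain = model.chain
    contig_len = genome.length(chain.chrom)
    pairs = []
    for s, e in chain.junction_chain():
        if s < 0 or e > contig_len:
            raise ValueError(
                f"{model.id}: junction ({s}, {e}) outside {chain.chrom}"
            )
        if chain.strand == "+":
            donor = genome.fetch(chain.chrom, s, s + 2, "+")
            acceptor = genome.fetch(chain.chrom, e - 2, e, "+")
        else:
            donor = genome.fetch(chain.chrom, e - 2, e, "-")
            acceptor = genome.fetch(chain.chrom, s, s + 2, "-")
        pairs.append(f"{donor}-{acceptor}")
    return pairs, all(p in CANONICAL_PAIRS for p in pairs)


def cage_annotate(
    model: TranscriptModel, summits: Sequence[int]
) -> tuple[int | None, bool | None, bool | None]:
    """Signed distance from the TSS to the nearest CAGE summit, plus flags.

    Positive distance means the TSS lies downstream of the summit in
    transcript orientation. Returns (None, None, None) when no summits are
    given. ``within_15bp`` uses |d| <= 15 (inclusive); ``beyond_250bp`` uses
    |d| > 250.
    """
    if not summits:
        return None, None, None
    tss = model.tss()
    nearest = min(summits, key=lambda s: (abs(tss - s), s))
    d = tss - nearest if model.chain.strand == "+" else nearest - tss
    return d, abs(d) <= 15, abs(d) > 250


def load_polya_motifs() -> list[str]:
    """The packaged human polyA signal hexamer list (AATAAA first)."""
    text = resources.files("capiso").joinpath("data/polya_motifs.txt").read_text()
    return [line.strip().upper() for line in text.splitlines() if line.strip()]


def polya_motif_scan(
    model: TranscriptModel,
    genome: cio.GenomeSource,
    motifs: Sequence[str] | None = None,
    window: int = 50,
) -> tuple[str, int] | None:
    """Best polyA motif in the `window` bp upstream of the transcript 3' end.

    The scan runs on the transcript strand; a motif counts only if fully
    inside the window, and the reported hit is the one whose end lies closest
    to the transcript end (distance in bp from motif end to transcript end).
    Returns None when no motif matches.
    """
    motifs = list(motifs) if motifs is not None else load_polya_motifs()
    if not motifs:
        raise ValueError("motif list is empty")
    chain = model.chain
    tes = model.tes()
    contig_len = genome.length(chain.chrom)
    if chain.strand == "+":
        gstart, gend = tes - window, tes
    else:
        gstart, gend = tes, tes + window
    if gstart < 0 or gend > contig_len:
        warnings.warn(
            f"{model.id}: polyA scan window truncated at contig boundary",
            stacklevel=2,
        )
        gstart, gend = max(0, gstart), min(contig_len, gend)
    seq = genome.fetch(chain.chrom, gstart, gend, chain.strand)

    best: tuple[int, int, str] | None = None
    for prio, motif in enumerate(motifs):
        start = seq.find(motif)
        while start != -1:
            dist = len(seq) - (start + len(motif))
            cand = (dist, prio, motif)
            if best is None or cand < best:
                best = cand
            start = seq.find(motif, start + 1)
    if best is None:
        return None
    return best[2], best[0]


def characterize(
    model: TranscriptModel,
    catalog: ReferenceCatalog,
    genome: cio.GenomeSource | None = None,
    summits: Sequence[int] | None = None,
    motifs: Sequence[str] | None = None,
    generic_ism: bool = False,
    polya_window: int = 50,
) -> ClassificationResult:
    """Full per-isoform annotation: category, canonicality, CAGE, polyA."""
    category, match = classify_isoform(model, catalog, generic_ism=generic_ism)
    result = ClassificationResult(
        isoform_id=model.id, category=category, matched_reference_id=match
    )
    if genome is not None:
        dinucs, all_canon = splice_canonicality(model, genome)
        result.junction_dinucleotides = dinucs
        result.all_canonical = all_canon
        hit = polya_motif_scan(model, genome, motifs=motifs, window=polya_window)
        if hit is not None:
            result.polya_motif, result.polya_motif_distance = hit
    if summits is not None:
        d, within, beyond = cage_annotate(model, summits)
        result.cage_distance_bp = d
        result.within_15bp = within
        result.beyond_250bp = beyond
    return result
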