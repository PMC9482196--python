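"""Readers and writers for BED12, GTF, FASTA and BED peak files.

Internally everything is 0-based half-open; GTF converts to/from 1-based
inclusive at the boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils

from .locus import ExonChain, TranscriptModel

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Bed12Error(ValueError):
    pass


def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise Bed12Error(f"line {lineno}: expected 12 BED columns, got {len(fields)}")
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        chrom_end = int(fields[2])
        name = fields[3]
        score = float(fields[4])
        strand = fields[5]
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise Bed12Error(f"line {lineno}: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise Bed12Error(f"line {lineno}: blockCount inconsistent with block lists")
    exons = []
    for rel, size in zip(starts, sizes):
        s = chrom_start + rel
        exons.append((s, s + size))
    if starts[0] != 0:
        raise Bed12Error(f"line {lineno}: first blockStart must be 0")
    if exons[-1][1] != chrom_end:
        raise Bed12Error(
            f"line {lineno}: blocks end at {exons[-1][1]} but chromEnd is {chrom_end}"
        )
    try:
        chain = ExonChain(chrom, strand, tuple(exons))
    except ValueError as exc:
        raise Bed12Error(f"line {lineno}: {exc}") from exc
    return TranscriptModel(id=name, chain=chain, rank_key=score)


def read_bed12(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read a BED12 file into transcript models (one per line).

    Malformed lines raise :class:`Bed12Error` naming the line number.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            models.append(_parse_bed12_line(line, lineno))
    return models


def bed12_line(model: TranscriptModel) -> str:
    chain = model.chain
    sizes = ",".join(str(e - s) for s, e in chain.exons)
    starts = ",".join(str(s - chain.start) for s, e in chain.exons)
    score = int(min(1000, model.total_count))
    return "\t".join(
        str(x)
        for x in (
            chain.chrom,
            chain.start,
            chain.end,
            model.id,
            score,
            chain.strand,
            chain.start,
            chain.end,
            "0",
            chain.n_exons,
            sizes,
            starts,
        )
    )


def write_bed12(models: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(bed12_line(m) + "\n")


def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read exon features of a GTF, grouped by transcript_id, as models.

    GTF is 1-based inclusive; coordinates are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ValueError(
                f"GTF exon at {feat.seqid}:{feat.start}-{feat.end} lacks transcript_id"
            ) from exc
        grouped.setdefault(tid, []).append(feat)
    models = []
    for tid, feats in grouped.items():
        feats.sort(key=lambda f: f.start)
        chrom = feats[0].seqid
        strand = feats[0].strand
        exons = tuple((f.start - 1, f.end) for f in feats)
        models.append(TranscriptModel(id=tid, chain=ExonChain(chrom, strand, exons)))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | os.PathLike,
              source: str = "capiso") -> None:
    """Write models as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            chain = m.chain
            for i, (s, e) in enumerate(chain.exons, start=1):
                attrs = f'gene_id "{m.id}"; transcript_id "{m.id}"; exon_number "{i}";'
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            chain.chrom, source, "exon", s + 1, e, ".",
                            chain.strand, ".", attrs,
                        )
                    )
                    + "\n"
                )


def read_peaks_bed(path: str | os.PathLike, chrom: str | None = None) -> list[int]:
    """Read a BED of peak summits, returning summit positions (the start field).

    If `chrom` is given, only summits on that sequence are returned.
    """
    positions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected at least 3 BED columns")
            if chrom is not None and fields[0] != chrom:
                continue
            positions.append(int(fields[1]))
    return sorted(positions)


class GenomeSource:
    """Stranded sequence access: fetch(chrom, start, end, strand).

    Returns the reverse complement on '-', i.e. the sequence reads 5'->3' in
    transcript orientation.
    """

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        raise NotImplementedError

    def length(self, chrom: str) -> int:
        raise NotImplementedError


class DictGenome(GenomeSource):
    """In-memory genome backed by a {chrom: sequence} dict."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = {k: v.upper() for k, v in seqs.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self.seqs:
            raise KeyError(f"unknown sequence {chrom!r}")
        seq = self.seqs[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])


class FastaGenome(GenomeSource):
    """Indexed FASTA access (pyfaidx) with strand-aware fetch."""

    def __init__(self, path: str | os.PathLike):
        import pyfaidx

        self.fasta = pyfaidx.Fasta(str(path))

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self.fasta:
            raise KeyError(f"unknown sequence {chrom!r}")
        seq = self.fasta[chrom][start:end].seq.upper()
        return revcomp(seq) if strand == "-" else seq

    def length(self, chrom: str) -> int:
        return len(self.fasta[chrom])


def read_fasta(path: str | os.PathLike) -> FastaGenome:
    return FastaGenome(path)


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
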