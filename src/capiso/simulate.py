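"""Synthetic locus, isoform set, and noisy full-length long reads.

The generator emulates the structure the analysis assumes: a multi-exon
minus-strand lncRNA locus on a ~14 kb contig with

* a configurable number of alternative start exons (default 9), the two
  proximal ones named "E3" and "E3.1" to carry the differentiation-driven
  TSS switch (E3.1-starting isoforms dominate early samples, E3-starting
  isoforms take over after induction);
* three alternative acceptor sites within one internal exon (the "E5"
  analogue, sites 1-3), with at least one pair of isoforms differing only by
  that acceptor;
* alternative polyA sites on the shared terminal exon (default 4), spaced
  2.5 kb apart so distinct 3'-end classes survive the wide stage-3 merge
  tolerance; every site is used by several isoforms;
* canonical GT-AG dinucleotides planted at every junction (on the transcript
  strand) and an AATAAA polyA signal planted 18 bp upstream of every polyA
  site;
* CAGE-like summits at each distinct TSS plus a decoy far from any start.

Every isoform has a distinct junction chain, so the chain <-> isoform map is
unambiguous: with noise off, collapse must recover the truth exactly and FSM
read assignment must reproduce the drawn per-isoform counts.

Reads are emitted as exon-chain alignment records plus a metadata sidecar
(subreads, cluster quality, polyA length, MAPQ, clipped bases), not as base
sequences: the analysis begins at aligned exon chains, and simulating
sequencing error plus realignment would add no test power. Noise consists of
terminal-end jitter (rounded normal, confined to the terminal exons so no
read ever gains or loses a junction), 5'-truncation dropping whole 5' exons,
metadata draws that fail each filter at stated rates, and injected
sense-strand and mono-exonic contaminant reads. All randomness flows from a
single integer seed through numpy's default PCG64 generator, so a fixed seed
gives byte-identical output across runs and platforms.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from .locus import ExonChain, GenomicInterval, LongReadRecord, TranscriptModel
from .quantify import FeatureAnnotation

DEFAULT_SAMPLES = ["Pro", "D0", "D1", "D3", "D9"]

# minus-strand locus layout (genomic coordinates, ascending = transcript 3'->5')
_TES_BASE = 300          # most distal (longest-transcript) polyA site
_TES_SPACING = 2500      # > stage-3 3' tolerance, so end classes stay distinct
_TERM_MARGIN = 400       # terminal exon extent beyond the most proximal polyA site
_E6_GAP, _E6_LEN = 200, 200
_E5_GAP, _E5_LEN = 200, 220     # E5 length at the shortest acceptor (site 3)
_ACCEPTOR_SPACING = 60          # site3 < site2 < site1 (exon lengthens)
_E4_GAP, _E4_LEN = 200, 200
_START_GAP, _START_LEN, _START_SPACING = 200, 250, 500
_MOTIF_OFFSET = 18       # polyA signal ends this many bp upstream of the 3' end
_START_WINDOW_PAD = 150  # start-exon annotation windows padded past the TSS


@dataclass
class NoiseParams:
    """Rates and magnitudes of the failure modes the read filters remove."""

    end_jitter_sd_5p: float = 25.0
    end_jitter_sd_3p: float = 15.0
    truncation_prob: float = 0.08
    polyA_len_mean: float = 60.0
    polyA_len_sd: float = 15.0
    polyA_short_prob: float = 0.04
    quality_low_prob: float = 0.05
    subread_mean: float = 5.0
    subread_fail_prob: float = 0.02
    frac_sense_contam: float = 0.05
    frac_mono_exon: float = 0.04
    mapq_low_prob: float = 0.03
    clip_high_prob: float = 0.03

    def __post_init__(self) -> None:
        for name in ("truncation_prob", "polyA_short_prob", "quality_low_prob",
                     "subread_fail_prob", "frac_sense_contam", "frac_mono_exon",
                     "mapq_low_prob", "clip_high_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")
        for name in ("end_jitter_sd_5p", "end_jitter_sd_3p", "polyA_len_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseParams":
        """Noise-free parameters: exact ends, no truncation or contamination,
        metadata that always passes the filters."""
        return cls(
            end_jitter_sd_5p=0.0,
            end_jitter_sd_3p=0.0,
            truncation_prob=0.0,
            polyA_len_sd=0.0,
            polyA_short_prob=0.0,
            quality_low_prob=0.0,
            subread_fail_prob=0.0,
            frac_sense_contam=0.0,
            frac_mono_exon=0.0,
            mapq_low_prob=0.0,
            clip_high_prob=0.0,
        )


@dataclass
class SimTruth:
    """Ground truth: genome, isoforms, abundance trajectories, noise model."""

    chrom: str
    strand: str
    genome: dict[str, str]
    locus: GenomicInterval
    isoforms: list[TranscriptModel]
    isoform_meta: dict[str, dict[str, str]]
    abundance: dict[str, dict[str, float]]
    samples: list[str]
    noise: NoiseParams
    seed: int
    annotation: FeatureAnnotation
    reference_ids: list[str]
    cage_summits: list[int]
    reference_extra: list[TranscriptModel] = field(default_factory=list)

    def junction_chains(self) -> set:
        return {iso.chain.chain_key() for iso in self.isoforms}

    def genome_source(self) -> cio.DictGenome:
        return cio.DictGenome(self.genome)

    def reference_models(self) -> list[TranscriptModel]:
        """The partial reference catalog: a subset of the true isoforms plus
        catalog-only transcripts (an annotated form never observed here)."""
        wanted = set(self.reference_ids)
        return [iso for iso in self.isoforms if iso.id in wanted] + list(
            self.reference_extra
        )

    def to_json(self, path) -> None:
        data = {
            "chrom": self.chrom,
            "strand": self.strand,
            "locus": [self.locus.start, self.locus.end],
            "samples": list(self.samples),
            "seed": self.seed,
            "noise": asdict(self.noise),
            "isoforms": {
                iso.id: [list(e) for e in iso.chain.exons] for iso in self.isoforms
            },
            "isoform_meta": self.isoform_meta,
            "abundance": self.abundance,
            "reference_ids": list(self.reference_ids),
            "reference_extra": {
                m.id: [list(e) for e in m.chain.exons] for m in self.reference_extra
            },
            "cage_summits": list(self.cage_summits),
            "annotation": {
                "start_exons": {
                    k: list(v) for k, v in self.annotation.start_exons.items()
                },
                "acceptors": dict(self.annotation.acceptors),
                "polya_classes": dict(self.annotation.polya_classes),
            },
            "genome": self.genome,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            data = json.load(fh)
        chrom, strand = data["chrom"], data["strand"]
        isoforms = [
            TranscriptModel(
                id=iso_id,
                chain=ExonChain(chrom, strand, tuple(tuple(e) for e in exons)),
            )
            for iso_id, exons in sorted(data["isoforms"].items())
        ]
        ann = data["annotation"]
        return cls(
            chrom=chrom,
            strand=strand,
            genome=data["genome"],
            locus=GenomicInterval(chrom, *data["locus"], strand),
            isoforms=isoforms,
            isoform_meta=data["isoform_meta"],
            abundance=data["abundance"],
            samples=data["samples"],
            noise=NoiseParams(**data["noise"]),
            seed=data["seed"],
            annotation=FeatureAnnotation(
                chrom=chrom,
                strand=strand,
                start_exons={k: tuple(v) for k, v in ann["start_exons"].items()},
                acceptors={k: int(v) for k, v in ann["acceptors"].items()},
                polya_classes={k: int(v) for k, v in ann["polya_classes"].items()},
            ),
            reference_ids=data["reference_ids"],
            cage_summits=data["cage_summits"],
            reference_extra=[
                TranscriptModel(
                    id=mid,
                    chain=ExonChain(chrom, strand, tuple(tuple(e) for e in exons)),
                )
                for mid, exons in sorted(data.get("reference_extra", {}).items())
            ],
        )


def _start_exon_labels(n: int) -> list[str]:
    """Labels in transcript 5'->3' (genomic descending) order."""
    named = ["E1", "E2", "E3", "E3.1"]
    if n <= len(named):
        return named[:n]
    return named + [f"N{i}" for i in range(1, n - len(named) + 1)]


def _switch_shares(labels: list[str], samples: list[str]) -> dict[str, np.ndarray]:
    """Per-sample start-exon abundance shares encoding the TSS switch."""
    n = len(samples)
    if n == 5:
        e31 = np.array([0.70, 0.70, 0.45, 0.30, 0.20])
        e3 = np.array([0.08, 0.08, 0.33, 0.46, 0.56])
    else:
        e31 = np.linspace(0.70, 0.20, n)
        e3 = np.linspace(0.08, 0.56, n)
    fixed = {"E3.1": e31, "E3": e3, "E2": np.full(n, 0.11), "E1": np.full(n, 0.04)}
    shares = {lab: fixed[lab] for lab in labels if lab in fixed}
    rest = [lab for lab in labels if lab not in fixed]
    used = sum(shares.values()) if shares else np.zeros(n)
    remainder = 1.0 - used
    if rest:
        for lab in rest:
            shares[lab] = remainder / len(rest)
    else:
        total = used
        shares = {lab: s / total for lab, s in shares.items()}
    return shares


def make_locus(
    n_start_exons: int = 9,
    n_polya_sites: int = 4,
    n_isoforms: int = 23,
    seed: int = 0,
    samples: list[str] | None = None,
    reads_per_sample: float = 1000.0,
    scenario: str = "switch",
    uniform_depth: float = 150.0,
    noise: NoiseParams | None = None,
    chrom: str = "chrS",
) -> SimTruth:
    """Build a deterministic ground-truth locus and isoform set.

    Each isoform combines one start exon, an optional internal exon on each
    side of the alternatively-spliced exon, one of its three acceptor sites,
    and one polyA site; all junction chains are distinct by construction.
    ``scenario`` selects the abundance model: "switch" plants the start-exon
    switch across the time course, "uniform" gives every isoform
    `uniform_depth` expected reads in every sample.
    """
    if n_isoforms < 1:
        raise ValueError("n_isoforms must be >= 1")
    if n_start_exons < 1 or n_polya_sites < 1:
        raise ValueError("need at least one start exon and one polyA site")
    if n_isoforms < n_start_exons:
        raise ValueError(
            f"{n_isoforms} isoforms cannot cover {n_start_exons} start exons"
        )
    if n_isoforms < n_polya_sites:
        raise ValueError(
            f"{n_isoforms} isoforms cannot cover {n_polya_sites} polyA sites"
        )
    if n_isoforms > 12 * n_start_exons:
        raise ValueError(
            "at most 12 structural variants per start exon are available"
        )
    if scenario not in ("switch", "uniform"):
        raise ValueError(f"unknown scenario {scenario!r}")
    samples = list(samples) if samples is not None else list(DEFAULT_SAMPLES)
    noise = noise if noise is not None else NoiseParams()

    # ---- layout ----------------------------------------------------------
    tes_sites = [_TES_BASE + j * _TES_SPACING for j in range(n_polya_sites)]
    term_end = max(tes_sites) + _TERM_MARGIN
    e6 = (term_end + _E6_GAP, term_end + _E6_GAP + _E6_LEN)
    e5_start = e6[1] + _E5_GAP
    acceptors = {
        "site3": e5_start + _E5_LEN,
        "site2": e5_start + _E5_LEN + _ACCEPTOR_SPACING,
        "site1": e5_start + _E5_LEN + 2 * _ACCEPTOR_SPACING,
    }
    e4_start = acceptors["site1"] + _E4_GAP
    e4 = (e4_start, e4_start + _E4_LEN)
    first_start = e4[1] + _START_GAP
    start_exons_asc = [
        (first_start + k * _START_SPACING, first_start + k * _START_SPACING + _START_LEN)
        for k in range(n_start_exons)
    ]
    genome_len = start_exons_asc[-1][1] + 300
    labels = _start_exon_labels(n_start_exons)  # transcript 5'->3'
    # genomic ascending index k -> label (E1 sits at the highest coordinates)
    label_by_k = {k: labels[n_start_exons - 1 - k] for k in range(n_start_exons)}
    exon_by_label = {label_by_k[k]: start_exons_asc[k] for k in range(n_start_exons)}

    # ---- isoform allocation ---------------------------------------------
    priority = [lab for lab in ("E3.1", "E3", "E2", "E1") if lab in labels]
    priority += [lab for lab in labels if lab not in priority]
    per_exon = {lab: n_isoforms // n_start_exons for lab in labels}
    for lab in priority[: n_isoforms % n_start_exons]:
        per_exon[lab] += 1

    # structural variants per start exon: (include E4, acceptor, include E6);
    # the first two differ only by the acceptor site
    combos = [
        (True, "site1", True), (True, "site3", True), (False, "site1", True),
        (True, "site1", False), (False, "site3", False), (True, "site2", True),
        (False, "site2", True), (True, "site2", False), (False, "site1", False),
        (True, "site3", False), (False, "site3", True), (False, "site2", False),
    ]

    # polyA-site assignment cycles so every site is used; where coverage
    # allows, the first exon's first two variants (the acceptor-only pair)
    # share their site so they differ by nothing but the acceptor
    polya_idx = [i % n_polya_sites for i in range(n_isoforms)]
    block = 0
    for lab in labels:
        if per_exon[lab] >= 2:
            trial = list(polya_idx)
            trial[block + 1] = trial[block]
            if len(set(trial)) == n_polya_sites:
                polya_idx = trial
            break
        block += per_exon[lab]

    isoforms: list[TranscriptModel] = []
    isoform_meta: dict[str, dict[str, str]] = {}
    iso_index = 0
    for lab in labels:  # transcript 5'->3' order: E1 first
        for use_e4, acc_name, use_e6 in combos[: per_exon[lab]]:
            tes = tes_sites[polya_idx[iso_index]]
            exons = [(tes, term_end)]
            if use_e6:
                exons.append(e6)
            exons.append((e5_start, acceptors[acc_name]))
            if use_e4:
                exons.append(e4)
            exons.append(exon_by_label[lab])
            iso_index += 1
            iso_id = f"T{iso_index:02d}"
            isoforms.append(
                TranscriptModel(
                    id=iso_id, chain=ExonChain(chrom, "-", tuple(exons))
                )
            )
            isoform_meta[iso_id] = {
                "start_exon": lab,
                "acceptor": acc_name,
                "polya": f"pA{tes_sites.index(tes) + 1}",
            }

    chains = {iso.chain.chain_key() for iso in isoforms}
    assert len(chains) == len(isoforms), "junction chains must be unique"

    # ---- abundance -------------------------------------------------------
    abundance: dict[str, dict[str, float]] = {s: {} for s in samples}
    if scenario == "uniform":
        for s in samples:
            for iso in isoforms:
                abundance[s][iso.id] = float(uniform_depth)
    else:
        shares = _switch_shares(labels, samples)
        members = {
            lab: [i for i in isoforms if isoform_meta[i.id]["start_exon"] == lab]
            for lab in labels
        }
        for si, s in enumerate(samples):
            for lab in labels:
                share = float(shares[lab][si])
                for iso in members[lab]:
                    abundance[s][iso.id] = reads_per_sample * share / len(members[lab])

    # ---- genome with planted signals ------------------------------------
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=genome_len)
    introns = set()
    for iso in isoforms:
        introns.update(iso.chain.introns())
    for s, e in introns:
        # transcript strand is '-': donor GT -> genomic AC at the intron end,
        # acceptor AG -> genomic CT at the intron start
        seq[e - 2], seq[e - 1] = "A", "C"
        seq[s], seq[s + 1] = "C", "T"
    for tes in tes_sites:
        motif = list("TTTATT")  # revcomp(AATAAA) on the minus strand
        seq[tes + _MOTIF_OFFSET : tes + _MOTIF_OFFSET + 6] = motif
    genome = {chrom: "".join(seq)}

    # pA classes in transcript 5'->3' order: the most proximal site first
    polya_classes = {
        f"pA{j + 1}": tes_sites[j] for j in range(n_polya_sites)
    }
    annotation = FeatureAnnotation(
        chrom=chrom,
        strand="-",
        start_exons={
            label_by_k[k]: (start_exons_asc[k][0],
                            start_exons_asc[k][1] + _START_WINDOW_PAD)
            for k in range(n_start_exons)
        },
        acceptors=dict(acceptors),
        polya_classes=polya_classes,
    )
    tss_values = sorted({iso.tss() for iso in isoforms})
    cage_summits = sorted(tss_values + [_TES_BASE])  # one decoy far from any TSS

    # Partial reference catalog: every other isoform, except those starting at
    # the novel cell-type-specific "E3.1" exon (its donor stays unannotated,
    # so E3.1-starting models classify as NNC). One catalog-only transcript
    # extends a non-reference isoform by an extra 5' exon, so that isoform
    # classifies as a 3'-anchored incomplete splice match.
    reference_ids = [
        iso.id
        for iso in isoforms[::2]
        if isoform_meta[iso.id]["start_exon"] != "E3.1"
    ]
    reference_extra: list[TranscriptModel] = []
    ref_set = set(reference_ids)
    for iso in isoforms:
        lab = isoform_meta[iso.id]["start_exon"]
        if iso.id in ref_set or lab == "E3.1":
            continue
        k = next(k for k, l in label_by_k.items() if l == lab)
        if k + 1 >= n_start_exons:
            continue
        upstream_exon = start_exons_asc[k + 1]
        extended = iso.chain.exons + (upstream_exon,)
        reference_extra.append(
            TranscriptModel(id="REF_EXT1", chain=ExonChain(chrom, "-", extended))
        )
        break

    return SimTruth(
        chrom=chrom,
        strand="-",
        genome=genome,
        locus=GenomicInterval(chrom, 0, genome_len, "-"),
        isoforms=isoforms,
        isoform_meta=isoform_meta,
        abundance=abundance,
        samples=samples,
        noise=noise,
        seed=seed,
        annotation=annotation,
        reference_ids=reference_ids,
        cage_summits=cage_summits,
        reference_extra=reference_extra,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReadSet:
    reads: list[LongReadRecord]
    drawn_counts: dict[str, dict[str, int]]
    n_truncated: int = 0
    n_contaminants: int = 0


def _jitter_end(rng, value: int, sd: float, lo: int, hi: int) -> int:
    if sd <= 0:
        return value
    return int(np.clip(value + round(rng.normal(0.0, sd)), lo, hi))


def _metadata(rng, noise: NoiseParams) -> dict:
    if noise.subread_fail_prob > 0 and rng.random() < noise.subread_fail_prob:
        subreads = 1
    else:
        subreads = 2 + int(rng.poisson(max(0.0, noise.subread_mean - 2)))
    if noise.quality_low_prob > 0 and rng.random() < noise.quality_low_prob:
        quality = round(float(rng.uniform(0.90, 0.9899)), 4)
    else:
        quality = round(float(rng.uniform(0.99, 1.0)), 4)
    if noise.polyA_short_prob > 0 and rng.random() < noise.polyA_short_prob:
        polya = int(rng.uniform(0, 20))
    else:
        polya = max(20, int(round(rng.normal(noise.polyA_len_mean,
                                             noise.polyA_len_sd))))
    mapq = 5 if (noise.mapq_low_prob > 0 and rng.random() < noise.mapq_low_prob) else 60
    if noise.clip_high_prob > 0 and rng.random() < noise.clip_high_prob:
        clipped = 50 + int(rng.poisson(40))
    else:
        clipped = int(rng.poisson(3))
    return dict(subreads=subreads, quality=quality, polya_len=polya,
                mapq=mapq, clipped=clipped)


def simulate_reads(
    truth: SimTruth, seed: int, noise: NoiseParams | None = None
) -> SimulatedReadSet:
    """Draw noisy full-length reads from the truth's abundance model.

    Per sample and isoform, the read count is Poisson around the expected
    abundance. Each read inherits its isoform's junction chain exactly; noise
    only jitters terminal ends (never crossing the first/last junction),
    truncates whole 5' exons, perturbs metadata, and injects sense-strand and
    mono-exon contaminants at the stated fractions.
    """
    noise = noise if noise is not None else truth.noise
    rng = np.random.default_rng(seed)
    genome_len = len(truth.genome[truth.chrom])
    reads: list[LongReadRecord] = []
    drawn: dict[str, dict[str, int]] = {}
    n_truncated = 0
    n_contaminants = 0
    counter = 0

    for sample in truth.samples:
        drawn[sample] = {}
        n_sample = 0
        for iso in truth.isoforms:
            lam = truth.abundance[sample].get(iso.id, 0.0)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            drawn[sample][iso.id] = n
            n_sample += n
            for _ in range(n):
                counter += 1
                exons = list(iso.chain.exons)
                if (
                    noise.truncation_prob > 0
                    and len(exons) > 1
                    and rng.random() < noise.truncation_prob
                ):
                    k = 1 + int(rng.poisson(0.5))
                    k = min(k, len(exons) - 1)
                    exons = exons[:-k]  # minus strand: 5' exons sit genomically last
                    n_truncated += 1
                # 5' end = genomic end of the last exon on the minus strand
                s_last, e_last = exons[-1]
                e_last = _jitter_end(rng, e_last, noise.end_jitter_sd_5p,
                                     s_last + 1, genome_len)
                exons[-1] = (s_last, e_last)
                s0, e0 = exons[0]
                s0 = _jitter_end(rng, s0, noise.end_jitter_sd_3p, 0, e0 - 1)
                exons[0] = (s0, e0)
                reads.append(
                    LongReadRecord(
                        read_id=f"{sample}/r{counter:06d}",
                        sample=sample,
                        chain=ExonChain(truth.chrom, "-", tuple(exons)),
                        **_metadata(rng, noise),
                    )
                )
        # contaminants, proportional to the sample's drawn depth
        n_sense = int(rng.binomial(n_sample, noise.frac_sense_contam)) \
            if noise.frac_sense_contam > 0 and n_sample else 0
        n_mono = int(rng.binomial(n_sample, noise.frac_mono_exon)) \
            if noise.frac_mono_exon > 0 and n_sample else 0
        for _ in range(n_sense):
            counter += 1
            n_contaminants += 1
            iso = truth.isoforms[int(rng.integers(len(truth.isoforms)))]
            reads.append(
                LongReadRecord(
                    read_id=f"{sample}/r{counter:06d}",
                    sample=sample,
                    chain=ExonChain(truth.chrom, "+", iso.chain.exons),
                    **_metadata(rng, noise),
                )
            )
        for _ in range(n_mono):
            counter += 1
            n_contaminants += 1
            iso = truth.isoforms[int(rng.integers(len(truth.isoforms)))]
            reads.append(
                LongReadRecord(
                    read_id=f"{sample}/r{counter:06d}",
                    sample=sample,
                    chain=ExonChain(truth.chrom, "-", (iso.chain.exons[0],)),
                    **_metadata(rng, noise),
                )
            )
    return SimulatedReadSet(
        reads=reads,
        drawn_counts=drawn,
        n_truncated=n_truncated,
        n_contaminants=n_contaminants,
    )


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def write_dataset(truth: SimTruth, simset: SimulatedReadSet, outdir) -> dict[str, str]:
    """Write the synthetic dataset; returns the paths written."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "truth": os.path.join(outdir, "truth.json"),
        "reads_bed": os.path.join(outdir, "reads.bed12"),
        "reads_meta": os.path.join(outdir, "reads_meta.tsv"),
        "reference_gtf": os.path.join(outdir, "reference.gtf"),
        "cage_bed": os.path.join(outdir, "cage_summits.bed"),
        "annotation": os.path.join(outdir, "annotation.yaml"),
    }
    cio.write_fasta(truth.genome, paths["genome"])
    truth.to_json(paths["truth"])
    with open(paths["reads_bed"], "w") as fh:
        for r in simset.reads:
            fh.write(cio.bed12_line(TranscriptModel(id=r.read_id, chain=r.chain)) + "\n")
    meta = pd.DataFrame(
        [
            (r.read_id, r.sample, r.subreads, r.quality, r.polya_len, r.mapq,
             r.clipped, int(r.is_primary))
            for r in simset.reads
        ],
        columns=["read_id", "sample", "subreads", "quality", "polyA_len",
                 "mapq", "clipped", "is_primary"],
    )
    meta.to_csv(paths["reads_meta"], sep="\t", index=False)
    cio.write_gtf(truth.reference_models(), paths["reference_gtf"])
    with open(paths["cage_bed"], "w") as fh:
        for i, pos in enumerate(truth.cage_summits, start=1):
            fh.write(f"{truth.chrom}\t{pos}\t{pos + 1}\tsummit{i}\n")
    truth.annotation.to_yaml(paths["annotation"])
    return paths


def read_reads(bed_path, meta_path) -> list[LongReadRecord]:
    """Join reads.bed12 with its metadata sidecar into read records."""
    models = cio.read_bed12(bed_path)
    meta = pd.read_csv(meta_path, sep="\t").set_index("read_id")
    reads = []
    for m in models:
        if m.id not in meta.index:
            raise ValueError(f"read {m.id!r}: no metadata row")
        row = meta.loc[m.id]
        reads.append(
            LongReadRecord(
                read_id=m.id,
                sample=str(row["sample"]),
                chain=m.chain,
                subreads=int(row["subreads"]),
                quality=float(row["quality"]),
                polya_len=int(row["polyA_len"]),
                mapq=int(row["mapq"]),
                clipped=int(row["clipped"]),
                is_primary=bool(row["is_primary"]),
            )
        )
    return reads
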