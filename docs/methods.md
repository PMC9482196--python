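# Methods

## Coordinate and strand conventions

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; GTF I/O converts to and from 1-based inclusive at the boundary. The
target lncRNA is antisense, so on the minus strand the transcript 5' end
(TSS) is the *higher* genomic coordinate (the exclusive end of the last
exon) and the 3' end (TES) the lower. Every 5'/3' tolerance — end wobble,
merge variability, CAGE distances, polyA windows — is applied in transcript
orientation. A transcript's identity is its junction chain: the ordered list
of intron (donor, acceptor boundary) coordinate pairs in transcript 5'→3'
order; terminal-exon outer ends never enter that identity.

Single-bp CAGE summits are represented by their BED start coordinate.
Mono-exonic records are representable throughout the data model but are
removed by the structure filter before collapse, and the classifier refuses
them (the category space is defined over spliced transcripts).

## Read filters

Three pure predicates, applied in a fixed order only for drop attribution
(they commute):

| filter | rule | reading |
|---|---|---|
| cluster quality | subreads ≥ 2, quality ≥ 0.99, polyA ≥ 20 bp | inclusive ("at least") |
| alignment | primary, chain inside target window, MAPQ > 20, clipped < 50 | strict ("above", "less than") |
| structure | ≥ 2 exons, on the target (antisense) strand | — |

The quality cutoff is treated as inclusive (≥ 0.99); the config documents
this choice. "Inside the target window" means the read's whole exon chain is
contained in the configured interval — the simplest defensible reading, with
capture off-target ends left to the clipping filter. The target strand is a
config value, not hard-coded, so the pipeline generalizes to sense-strand
loci.

## Collapse and merge

Stage 1 (within sample) groups reads by exact junction chain — junction
coordinates are never wobbled, because CCS-polished (and simulated)
junctions are exact, and exact grouping makes the procedure
order-independent — then clusters terminal ends within ±100 bp (both ends).
A chain that is a strict 3'-anchored suffix of a longer chain is a separate
group by construction and is never absorbed ("don't merge 5'-shorter"):
5'-truncated molecules must not inflate full-length models. Representative
ends are the modal end over member reads, ties resolved toward the more
transcript-extreme value.

Stage 2 admits models with ≥ 50 full-length reads *within one sample* and
unifies identical chains across samples when their ends agree within the
stage-1 wobbles, keeping per-sample counts side by side. Stage 3 merges on
internal junctions only, widening end variability to 300 bp (5') and
2000 bp (3'); the surviving representative — which donates the reported
ends — is the model whose best-supporting sample ranks highest when
libraries are ordered by their polyadenylated on-target read count (ties by
sample name), then by read count, then id.

End clustering everywhere uses representative-bounded components: the
representative is fixed first and membership is re-checked against it rather
than chained pairwise. This bounds tolerance drift, makes the partition
deterministic, and makes all merge stages idempotent. Model count is
non-increasing across stages and read support is conserved within kept
models. The stage-2 end-concordance requirement makes the wide stage-3
tolerances meaningful: distinct 5'/3' end variants of the same chain survive
the cross-sample merge and are only reconciled by the final
internal-junction merge.

## Classification

Categories relative to a reference catalog (the union of reference models'
junction chains, donor sites and acceptor sites, treated as one
undifferentiated set):

* **FSM** — identical junction chain; terminal ends free to differ by any
  amount.
* **ISM** — strict, contiguous, *3'-anchored* sub-chain of a reference
  (fewer 5' exons, internal junctions perfectly consistent). This is
  narrower than generic incomplete-match definitions; a `generic_ism` switch
  accepts any contiguous sub-chain for comparability.
* **NIC** — all donor and acceptor sites known, combination novel.
* **NNC** — at least one unknown donor or acceptor site.

Every multi-exon model receives exactly one category. FSM/ISM ties among
references are resolved by nearest TSS, then reference id — an arbitrary but
deterministic rule. Splice-site dinucleotides are read on the transcript
strand; the canonical set is {GT‑AG, GC‑AG, AT‑AC}. CAGE distance is signed
positive when the TSS lies downstream of the nearest summit in transcript
orientation; `within_15bp` is inclusive (|d| ≤ 15), `beyond_250bp` strict
(|d| > 250). The polyA scan searches the 50 bp of genomic sequence upstream
of the 3' end on the transcript strand (the common convention for this
annotation; the window is configurable), counts a motif only if fully inside
the window, and reports the hit whose end lies closest to the transcript
end. The packaged motif list is the standard 12-hexamer human polyA signal
set with AATAAA and ATTAAA first.

## Quantification

Reads count for an isoform only on a full-splice-match basis — identical
junction chain, terminal ends free. If several final models shared a chain
the tie would go to the nearest 3' end, then 5' end; an `ism_rescue` switch
(off by default, matching the strict FSM-only counting) also counts
3'-truncation-consistent reads. Unassigned and mono-exon reads are tallied
per sample, and assigned + unassigned equals the filtered read count.

High-confidence isoforms require > 100 cumulative reads (strict) and
detection in ≥ 2 samples. Usage statistics are computed over assigned reads
of high-confidence isoforms by default (`usage_high_confidence_only`
switches to all assigned reads). Start exons are "reported" when their
cumulative read count exceeds 500 (strict). The junction-prevalence
statistic counts samples with ≥ 10 spanning reads per junction; the
threshold and its strictness are configurable because "more than 10" and
"at least 10" both appear as common phrasings of this filter — the default
is the inclusive ≥ 10.

3'-end classes are defined by named polyA-site positions on the terminal
exon; an isoform's end is binned to the nearest class position, and ends
lying transcript-upstream of every class by more than `upstream_slack`
(default 100 bp) fall into "other". All usage tables are proportions summing
to 1 over their buckets (including "other") for every non-empty sample.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
base-level sequencing: reads are emitted directly as exon-chain alignment
records with a metadata sidecar, because the computation begins at aligned
exon chains and simulating sequencing error plus realignment would add no
test power. An optional FASTA of the genome is always written.

The default locus is a ~14 kb minus-strand gene: a shared terminal exon with
4 polyA sites spaced 2.5 kb apart (wider than the 2 kb stage-3 tolerance, so
distinct 3'-end classes survive the merge), one internal exon with three
alternative acceptor sites 60 bp apart, two optional internal exons, and 9
alternative start exons 500 bp apart (labelled E1, E2, E3, E3.1, N1–N5; the
novel E3.1 analogue is excluded from the reference catalog). Each isoform
combines one start exon, one acceptor, an optional exon on each side, and
one polyA site; all 23 default junction chains are distinct by construction,
which keeps the chain → isoform map unambiguous — the property that lets
noise-free collapse recover the truth exactly and lets FSM counting
reproduce the drawn per-isoform counts. The generator guarantees a pair of
isoforms differing *only* by the alternative acceptor; 3'-end (polyA)
variation is carried across isoforms with different chains, because two
transcripts differing in nothing but the cleavage site share a junction
chain and would be indistinguishable to chain-based collapse and counting.
GT‑AG dinucleotides are planted at every junction on the transcript strand,
an AATAAA signal ends 18 bp upstream of every polyA site, and CAGE-like
summits sit at every distinct TSS plus one decoy.

Abundance scenarios: `uniform` gives every isoform a constant expected depth
(default 150 reads/sample — enough that every isoform clears the 50-read
merge and 100-read confidence cutoffs with a wide margin); `switch` (the
default, 1000 reads/sample) plants the differentiation-driven TSS switch —
E3.1-starting isoforms at 70% of reads in Pro/D0 falling to 20% at D9,
E3-starting isoforms rising from 8% to 56%, E2 fixed at 11% and E1 at 4%
(so only E2, E3 and E3.1 clear the 500-read reporting cutoff), the rest
spread over the minor start exons. Read counts per isoform and sample are
Poisson around these expectations.

Noise parameters model exactly the failure modes the filters remove, with
defaults chosen to resemble a clustered CCS library: terminal-end jitter
(rounded normal, sd 25 bp at 5' and 15 bp at 3' — enough to exercise the
100 bp wobble without crossing it in bulk; jitter is clamped so it never
crosses the first/last junction, hence no simulated read ever gains or loses
a junction), 5'-truncation dropping whole 5' exons with probability 0.08,
failure rates of a few percent each for subread count, cluster quality,
polyA length, MAPQ and clipping, and 5%/4% sense-strand and mono-exon
contaminant reads. `NoiseParams.zero()` switches all of it off while keeping
metadata that passes every filter. All randomness flows from one integer
seed through numpy's PCG64 generator, so output is byte-identical across
runs and platforms. The simulator does not model base-call errors, inexact
(wobbly) junctions, chimeric reads or barcode hopping — so passing tests
demonstrate the correctness of the pipeline's logic under its stated
assumptions, not robustness to junction-level alignment noise.

## Verification strategy and problem sizes

Every non-trivial rule is checked against an independent oracle in the test
suite: the category rules against an exhaustive enumerator over ~800
perturbed junction combinations, the stage-3 merge against a brute-force
partition of up to 8 models over 20 random instances, the filters against a
direct restatement of their predicates on a full noisy simulation, and the
statistical recovery of the planted TSS switch against 3σ multinomial bounds
over 100 seeded replicates at 1000 reads/sample. The noise-free
truth-recovery run uses 23 isoforms × 5 samples × 150 reads (~17,000 reads),
which completes in a few seconds; these sizes give the statistical checks
comfortable power while keeping the whole suite around a minute.

## Known limitations

* Junction coordinates must be exact; the pipeline assumes polished input
  (clustered CCS) and does not rescue wobbly splice sites.
* The ISM definition is 3'-anchored by design; generic sub-chain matching is
  available but off by default.
* The cross-sample merge requires end concordance at the stage-1 wobble;
  loci with extreme within-chain end dispersion will carry more models into
  stage 3 than a tolerance-free unification would.
* Mono-exonic transcripts are out of scope end to end (filtered, not
  modelled).
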