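# capiso

Targeted long-read (capture-seq) isoform discovery, classification and usage
quantification for a single lncRNA locus.

## The problem

Long non-coding RNA loci such as *HOTAIR* — an antisense, minus-strand
transcript in the *HOXC* cluster — express a pool of isoforms generated by
alternative transcription start sites (TSSs), alternative splice-site usage
and alternative polyadenylation. Short reads cannot resolve which of these
events co-occur on one molecule; targeted PacBio capture sequencing of
full-length polyadenylated transcripts can, but turning a few thousand
clustered CCS reads into a trustworthy isoform catalog requires careful read
filtering, collapse of redundant models, reference-relative classification,
and read-count-based confidence filtering. `capiso` implements that pipeline
as a tested, reusable library and CLI for anyone characterizing the isoform
repertoire of a single locus across a sample series (here, an adipose
stem-cell differentiation time course: Pro, D0, D1, D3, D9).

## The method

Reads arrive as stranded exon chains on the genome (BED12) plus per-read
CCS/alignment metadata. Writing a transcript's introns in transcript
5'→3' order as its **junction chain** `J = ((d_1,a_1), …, (d_{n-1},a_{n-1}))`,
the pipeline is:

1. **Filter** — keep reads with subreads ≥ 2, cluster quality ≥ 0.99,
   polyA tail ≥ 20 bp, primary alignment inside the target window with
   MAPQ > 20 and < 50 clipped bases, ≥ 2 exons, antisense strand.
2. **Collapse (within sample)** — group reads by identical `J`; merge
   terminal ends within ±100 bp wobble; never merge a chain that is a strict
   3'-anchored suffix of a longer one (5'-truncated molecules stay separate).
3. **Merge (across samples)** — models with ≥ 50 full-length reads within one
   sample enter; identical chains with concordant ends are unified, then a
   final merge on *internal junctions only* widens end variability to 300 bp
   (5') and 2000 bp (3'), with the representative ends taken from the library
   ranked highest by polyadenylated on-target read count.
4. **Classify** against a reference catalog:
   FSM (identical `J`), ISM (strict 3'-anchored sub-chain of a reference),
   NIC (all donor/acceptor sites known, combination novel), NNC (≥ 1 unknown
   site); plus splice-site dinucleotides (canonical GT‑AG/GC‑AG/AT‑AC on the
   transcript strand), signed distance from each TSS to the nearest CAGE
   summit (within 15 bp / beyond 250 bp flags), and polyA signal motifs
   (AATAAA etc.) within 50 bp upstream of the 3' end.
5. **Quantify** — reads count for an isoform only as full splice matches
   (terminal ends free); high-confidence isoforms need > 100 cumulative reads
   in ≥ 2 samples; usage tables cover start exons (reported when cumulative
   reads > 500), alternative acceptor sites within one exon, polyA 3'-end
   classes, and junction sample prevalence (samples with ≥ 10 spanning
   reads).

A fully seeded synthetic-data generator builds a ~14 kb minus-strand locus
with 9 alternative start exons, 3 alternative acceptors in one internal exon,
4 polyA sites, planted GT‑AG junctions, planted AATAAA signals, CAGE-like
summits, and a differentiation-driven TSS switch (start exon E3.1 falling
from 70% to 20% of reads while E3 rises), so every stage is testable without
any download.

## Worked example

```python
from capiso.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=42, outdir="demo_out"))
r = result.report
print(f"reads simulated : {r.n_reads_input}")
print(f"reads kept      : {r.filter['n_kept']}  (dropped {r.filter['dropped_by_reason']})")
print(f"final isoforms  : {r.n_models_stage3}")
print(f"high-confidence : {len(result.high_confidence)}")
print(f"categories      : {r.category_tally}")
print(f"start exons >500: {r.reported_start_exons}")
```

prints

```
reads simulated : 5380
reads kept      : 4158  (dropped {'cluster_quality': 545, 'alignment': 287, 'structure': 390})
final isoforms  : 6
high-confidence : 6
categories      : {'FSM': 2, 'ISM': 0, 'NIC': 1, 'NNC': 3}
start exons >500: ['E3.1', 'E3']
```

At the default 1000 reads/sample most of the 23 simulated isoforms are too
rare to reach the 50-read merge threshold, so only the 6 abundant ones
survive — the same behaviour that takes the real locus from thousands of
clustered reads to a compact catalog. Raising the depth and switching off
noise recovers the truth exactly:

```python
from capiso.pipeline import RunConfig, SimulationConfig, run_pipeline
from capiso.simulate import NoiseParams

cfg = RunConfig(seed=1, outdir="demo_zero",
                simulation=SimulationConfig(scenario="uniform", uniform_depth=150.0),
                noise=NoiseParams.zero())
res = run_pipeline(cfg)
# res.report.truth_recovered -> True; 23 isoforms, all 23 high-confidence
```

The same pipeline is available from the shell:

```bash
capiso simulate --seed 3 --outdir sim/
capiso run --seed 42 --outdir out/
capiso validate --config my_config.yaml
```

`out/` then contains `models.bed12`, `counts.tsv`, `classification.tsv`,
`start_exon_usage.tsv`, `acceptor_usage.tsv`, `end_class_usage.tsv`,
`prevalence.tsv`, `filter_report.json` and `run_report.json`.

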