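"""End-to-end orchestration: simulate -> filter -> collapse -> merge ->
classify -> quantify, with a machine-readable run report.

The pipeline consumes read alignments as exon chains (BED12 + metadata TSV);
sample order is the time-course order given in the config, never inferred
from names. Given the same inputs and seed the run is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from . import classify as ccl
from . import collapse as ccol
from . import filters as cflt
from . import io as cio
from . import quantify as cq
from . import simulate as csim
from .locus import GenomicInterval

log = logging.getLogger("capiso")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_start_exons: int = 9
    n_polya_sites: int = 4
    n_isoforms: int = 23
    reads_per_sample: float = 1000.0
    scenario: str = "switch"
    uniform_depth: float = 150.0


@dataclass
class ClassificationConfig:
    generic_ism: bool = False
    polya_window: int = 50


@dataclass
class InputPaths:
    reads_bed: str | None = None
    reads_meta: str | None = None
    genome_fa: str | None = None
    reference_gtf: str | None = None
    cage_bed: str | None = None
    annotation_yaml: str | None = None
    truth_json: str | None = None


@dataclass
class RunConfig:
    seed: int = 42
    outdir: str = "capiso_out"
    samples: list[str] = field(default_factory=lambda: list(csim.DEFAULT_SAMPLES))
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    noise: csim.NoiseParams = field(default_factory=csim.NoiseParams)
    filters: cflt.FilterConfig = field(default_factory=cflt.FilterConfig)
    collapse: ccol.CollapseConfig = field(default_factory=ccol.CollapseConfig)
    quant: cq.QuantConfig = field(default_factory=cq.QuantConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    inputs: InputPaths = field(default_factory=InputPaths)

    def to_dict(self) -> dict:
        data = asdict(self)
        region = data["filters"]["target_region"]
        if region is not None:
            data["filters"]["target_region"] = [
                region["chrom"], region["start"], region["end"], region["strand"]
            ]
        return data

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")

        def sub(key, klass):
            section = dict(data.get(key) or {})
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(section) - names
            if bad:
                raise ConfigError(f"unknown fields in {key!r}: {sorted(bad)}")
            if key == "filters" and section.get("target_region") is not None:
                chrom, start, end, strand = section["target_region"]
                section["target_region"] = GenomicInterval(chrom, start, end, strand)
            try:
                return klass(**section)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid {key!r} section: {exc}") from exc

        return cls(
            seed=int(data.get("seed", 42)),
            outdir=str(data.get("outdir", "capiso_out")),
            samples=list(data.get("samples", csim.DEFAULT_SAMPLES)),
            simulate=bool(data.get("simulate", True)),
            simulation=sub("simulation", SimulationConfig),
            noise=sub("noise", csim.NoiseParams),
            filters=sub("filters", cflt.FilterConfig),
            collapse=sub("collapse", ccol.CollapseConfig),
            quant=sub("quant", cq.QuantConfig),
            classification=sub("classification", ClassificationConfig),
            inputs=sub("inputs", InputPaths),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)


#: (section, field, standard default) used by `validate_config` to echo the
#: effective thresholds against the procedure's standard values
_THRESHOLD_DEFAULTS = [
    ("filters", "min_subreads", 2),
    ("filters", "min_quality", 0.99),
    ("filters", "min_polya", 20),
    ("filters", "min_mapq_exclusive", 20),
    ("filters", "max_clipped_exclusive", 50),
    ("collapse", "wobble5_stage1", 100),
    ("collapse", "wobble3_stage1", 100),
    ("collapse", "min_fl_for_merge", 50),
    ("collapse", "tol5_stage3", 300),
    ("collapse", "tol3_stage3", 2000),
    ("quant", "min_reads_exclusive", 100),
    ("quant", "min_samples", 2),
    ("quant", "min_start_exon_reads", 500),
    ("quant", "junction_prevalence_min_reads", 10),
]


def validate_config(data: dict) -> tuple[list[str], list[str], list[str]]:
    """Validate a raw config mapping; returns (errors, warnings, info)."""
    errors: list[str] = []
    warnings_: list[str] = []
    info: list[str] = []
    try:
        cfg = RunConfig.from_dict(data)
    except ConfigError as exc:
        return [str(exc)], [], []
    if not cfg.samples:
        errors.append("samples: at least one sample required")
    if len(set(cfg.samples)) != len(cfg.samples):
        errors.append("samples: duplicate sample names")
    for section, name, default in _THRESHOLD_DEFAULTS:
        value = getattr(getattr(cfg, section), name)
        info.append(f"{section}.{name} = {value} (standard {default})")
        if value != default:
            warnings_.append(
                f"{section}.{name} = {value} differs from the standard {default}"
            )
    return errors, warnings_, info


@dataclass
class RunReport:
    seed: int
    config_hash: str
    version: str
    samples: list[str]
    n_reads_input: int = 0
    filter: dict = field(default_factory=dict)
    n_models_stage1: dict[str, int] = field(default_factory=dict)
    n_models_stage2: int = 0
    n_models_stage3: int = 0
    library_rank: dict[str, int] = field(default_factory=dict)
    category_tally: dict[str, int] = field(default_factory=dict)
    high_confidence: list[str] = field(default_factory=list)
    reported_start_exons: list[str] = field(default_factory=list)
    assigned: dict[str, int] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)
    truth_recovered: bool | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class PipelineResult:
    report: RunReport
    final_models: list
    counts: pd.DataFrame
    high_confidence: list[str]
    classification: pd.DataFrame | None
    truth: csim.SimTruth | None


def _counts_frame(models, samples) -> pd.DataFrame:
    return pd.DataFrame(
        [[m.counts.get(s, 0) for s in samples] for m in models],
        index=[m.id for m in models],
        columns=samples,
        dtype=int,
    )


def run_pipeline(config: RunConfig, outdir: str | None = None) -> PipelineResult:
    """Run all stages, writing every intermediate artifact under `outdir`."""
    outdir = outdir or config.outdir
    os.makedirs(outdir, exist_ok=True)
    report = RunReport(
        seed=config.seed,
        config_hash=config.config_hash(),
        version=__version__,
        samples=list(config.samples),
    )

    # ---- stage 0: obtain reads ------------------------------------------
    truth: csim.SimTruth | None = None
    genome: cio.GenomeSource | None = None
    summits: list[int] | None = None
    annotation: cq.FeatureAnnotation | None = None
    reference_models = None
    if config.simulate:
        log.info("simulating dataset (seed %d)", config.seed)
        sim = config.simulation
        truth = csim.make_locus(
            n_start_exons=sim.n_start_exons,
            n_polya_sites=sim.n_polya_sites,
            n_isoforms=sim.n_isoforms,
            seed=config.seed,
            samples=config.samples,
            reads_per_sample=sim.reads_per_sample,
            scenario=sim.scenario,
            uniform_depth=sim.uniform_depth,
            noise=config.noise,
        )
        simset = csim.simulate_reads(truth, seed=config.seed + 1)
        csim.write_dataset(truth, simset, os.path.join(outdir, "sim"))
        reads = simset.reads
        genome = truth.genome_source()
        summits = truth.cage_summits
        annotation = truth.annotation
        reference_models = truth.reference_models()
    else:
        paths = config.inputs
        if not paths.reads_bed or not paths.reads_meta:
            raise ConfigError("inputs.reads_bed and inputs.reads_meta are required")
        reads = csim.read_reads(paths.reads_bed, paths.reads_meta)
        if paths.truth_json:
            truth = csim.SimTruth.from_json(paths.truth_json)
        if paths.genome_fa:
            genome = cio.read_fasta(paths.genome_fa)
        if paths.reference_gtf:
            reference_models = cio.read_gtf(paths.reference_gtf)
        if paths.cage_bed:
            summits = cio.read_peaks_bed(paths.cage_bed)
        if paths.annotation_yaml:
            annotation = cq.FeatureAnnotation.from_yaml(paths.annotation_yaml)
    report.n_reads_input = len(reads)

    # ---- stage 1: filters ------------------------------------------------
    fcfg = config.filters
    if fcfg.target_region is None and truth is not None:
        fcfg = dataclasses.replace(
            fcfg, target_region=truth.locus, target_strand=truth.strand
        )
    kept, freport = cflt.apply_filters(reads, fcfg)
    report.filter = freport.to_dict()
    log.info("filters kept %d / %d reads", freport.n_kept, freport.n_input)
    pd.DataFrame(freport.dropped_reads, columns=["read_id", "first_fail"]).to_csv(
        os.path.join(outdir, "dropped_reads.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "filter_report.json"), "w") as fh:
        json.dump(freport.to_dict(), fh, indent=1, sort_keys=True)

    # ---- stages 2-4: collapse and merge ---------------------------------
    rank = ccol.rank_from_reads(kept)
    report.library_rank = rank
    by_sample: dict[str, list] = {s: [] for s in config.samples}
    for r in kept:
        by_sample.setdefault(r.sample, []).append(r)
    stage1 = {
        s: ccol.collapse_sample(rs, config.collapse) if rs else []
        for s, rs in by_sample.items()
    }
    report.n_models_stage1 = {s: len(ms) for s, ms in stage1.items()}
    all_stage1 = [m for s in config.samples for m in stage1.get(s, [])]
    cio.write_bed12(all_stage1, os.path.join(outdir, "stage1_models.bed12"))

    stage2 = ccol.merge_samples(stage1, config.collapse)
    report.n_models_stage2 = len(stage2)
    cio.write_bed12(stage2, os.path.join(outdir, "stage2_models.bed12"))

    final = ccol.merge_internal_junctions(stage2, config.collapse, rank)
    report.n_models_stage3 = len(final)
    cio.write_bed12(final, os.path.join(outdir, "models.bed12"))
    provenance = {
        m.id: {"members": list(m.members), "counts": dict(m.counts)} for m in final
    }
    with open(os.path.join(outdir, "merge_provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    _counts_frame(final, config.samples).to_csv(
        os.path.join(outdir, "model_support.tsv"), sep="\t"
    )
    if truth is not None:
        report.truth_recovered = (
            {m.chain.chain_key() for m in final} == truth.junction_chains()
        )

    # ---- stage 5: classification ----------------------------------------
    classification = None
    if reference_models:
        catalog = ccl.ReferenceCatalog(models=reference_models)
        rows = []
        for m in final:
            res = ccl.characterize(
                m,
                catalog,
                genome=genome,
                summits=summits,
                generic_ism=config.classification.generic_ism,
                polya_window=config.classification.polya_window,
            )
            rows.append(
                {
                    "isoform_id": res.isoform_id,
                    "category": res.category,
                    "matched_reference_id": res.matched_reference_id,
                    "all_canonical": res.all_canonical,
                    "cage_distance_bp": res.cage_distance_bp,
                    "within_15bp": res.within_15bp,
                    "beyond_250bp": res.beyond_250bp,
                    "polyA_motif": res.polya_motif,
                    "polyA_motif_distance": res.polya_motif_distance,
                }
            )
        columns = [
            "isoform_id", "category", "matched_reference_id", "all_canonical",
            "cage_distance_bp", "within_15bp", "beyond_250bp", "polyA_motif",
            "polyA_motif_distance",
        ]
        classification = pd.DataFrame(rows, columns=columns).set_index("isoform_id")
        classification.to_csv(os.path.join(outdir, "classification.tsv"), sep="\t")
        tally = classification["category"].value_counts().to_dict()
        report.category_tally = {c: int(tally.get(c, 0)) for c in ccl.CATEGORIES}

    # ---- stage 6: quantification ----------------------------------------
    counts, unassigned = cq.assign_reads(
        kept, final, samples=config.samples, ism_rescue=config.quant.ism_rescue
    )
    counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    report.assigned = {s: int(counts[s].sum()) for s in config.samples}
    report.unassigned = {s: int(unassigned[s]) for s in config.samples}
    hc = cq.high_confidence_filter(counts, config.quant)
    report.high_confidence = hc
    cq.isoform_proportions(counts).to_csv(
        os.path.join(outdir, "proportions.tsv"), sep="\t"
    )
    usage_counts = counts.loc[hc] if config.quant.usage_high_confidence_only else counts
    if annotation is not None and annotation.start_exons:
        usage = cq.start_exon_usage(final, usage_counts, annotation, config.quant)
        usage.totals.to_csv(os.path.join(outdir, "start_exon_usage.tsv"), sep="\t")
        usage.proportions.to_csv(
            os.path.join(outdir, "start_exon_proportions.tsv"), sep="\t"
        )
        report.reported_start_exons = usage.reported
    if annotation is not None and annotation.acceptors:
        cq.acceptor_site_usage(final, usage_counts, annotation).to_csv(
            os.path.join(outdir, "acceptor_usage.tsv"), sep="\t"
        )
    if annotation is not None and annotation.polya_classes:
        cq.end_class_usage(final, usage_counts, annotation).to_csv(
            os.path.join(outdir, "end_class_usage.tsv"), sep="\t"
        )
    jtable = cq.junction_count_table(kept)
    jtable.to_csv(os.path.join(outdir, "junction_counts.tsv"), sep="\t", index=False)
    cq.junction_prevalence(jtable, config.quant).rename("n_samples").to_csv(
        os.path.join(outdir, "prevalence.tsv"), sep="\t"
    )

    report.to_json(os.path.join(outdir, "run_report.json"))
    return PipelineResult(
        report=report,
        final_models=final,
        counts=counts,
        high_confidence=hc,
        classification=classification,
        truth=truth,
    )
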