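"""End-to-end pipeline: simulate -> monomerize -> classify -> hor ->
phylo -> enrich -> report.

A single global seed fans out to per-stage seeds by fixed offsets, so a
stage rerun in isolation reproduces its outputs. Every run writes a
manifest (config hash, seed, package version) and a run.log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import pandas as pd

from . import __version__
from .enrich import EnrichParams, assign_reads, enrichment_ratio, qpcr_table
from .family import (
    SamplingParams,
    classify_subfamily,
    cluster_variants,
    refine_variant_clusters,
    sample_monomers,
)
from .hor import HORCall, HORParams, build_barcode, segment_and_call, symbolize
from .monomer import MonomerHit, decompose, derive_consensus, detect_period
from .phylo import PhyloParams, bootstrap_support, star_align
from .repeatio import (
    IntervalRecord,
    SeqRecord,
    setup_run_logging,
    write_bed,
    write_fasta,
    write_fastq,
    write_tsv,
)
from .synthetic_data import (
    GroundTruth,
    ReadSimConfig,
    build_karyotype,
    default_family_consensus,
    default_karyotype_specs,
    simulate_qpcr_counts,
    simulate_reads,
)

#: Study-like true fold enrichments (and per-target assay noise) for the
#: synthetic qPCR experiment: four centromere-associated targets strongly
#: enriched, the centromeric retrotransposon weakly and noisily enriched,
#: and a non-centromeric repeat as the negative control.
DEFAULT_QPCR_FOLDS = {
    "CentGm-1": (7.3, 0.15),
    "CentGm-4": (12.8, 0.15),
    "GsCL137": (8.0, 0.15),
    "GsCL107": (6.1, 0.15),
    "GmCR": (3.0, 0.5),
    "STR120": (1.0, 0.15),
}
QPCR_CONTROL = "STR120"

ALL_STAGES = ("simulate", "monomerize", "classify", "hor", "phylo", "enrich", "qpcr", "report")


@dataclass
class PipelineConfig:
    outdir: str = "cenbarcode_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    n_chromosomes: int = 20
    sub_rate: float = 0.05
    indel_rate: float = 0.0
    variant_divergence: float = 0.08
    # clustering threshold sits between the expected within-variant
    # (~90%) and cross-variant (~83%) copy identities at the default rates
    cluster_identity_threshold: float = 87.0
    min_identity: float = 60.0
    period_range: tuple[int, int] = (10, 500)
    hor_params: HORParams = field(default_factory=HORParams)
    n_monomers_sample: int = 10
    bootstrap_replicates: int = 25
    read_pairs: int = 1000
    enrichment_rho: float = 8.0
    # total flanking sequence as a multiple of array length; the pipeline
    # genome is deliberately flank-heavy (repeat fraction ~5%) so the
    # ChIP/input enrichment ratio is informative rather than saturated
    flank_frac: float = 20.0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ArrayAnalysis:
    """Everything the pipeline derives from one chromosome's array."""

    chromosome: str
    consensus: str
    subfamily: str
    hits: list[MonomerHit]
    symbols: str
    calls: list[HORCall]


def analyze_array(
    chromosome: str,
    array: str,
    period_range: tuple[int, int] = (10, 500),
    min_identity: float = 60.0,
    cluster_identity_threshold: float = 87.0,
    hor_params: HORParams | None = None,
) -> ArrayAnalysis:
    """Run the consensus-free analysis chain on one satellite array:
    period detection, consensus derivation, monomer tiling, variant
    clustering, and HOR calling."""
    lo, hi = period_range
    hi = min(hi, max(lo, len(array) // 3))
    estimate = detect_period(array, lo, hi)
    consensus = derive_consensus(array, estimate.period)
    hits = decompose(array, consensus, min_identity=min_identity)
    full = [h.sequence for h in hits if not h.partial]
    labeling = refine_variant_clusters(
        full, cluster_variants(full, identity_threshold=cluster_identity_threshold)
    )
    symbols = symbolize(hits, labeling)
    calls = segment_and_call(chromosome, symbols, hits, hor_params)
    return ArrayAnalysis(
        chromosome=chromosome,
        consensus=consensus,
        subfamily=classify_subfamily(consensus),
        hits=hits,
        symbols=symbols,
        calls=calls,
    )


def array_span(ground_truth: GroundTruth, chromosome: str) -> tuple[int, int]:
    """Satellite array extent on a chromosome, from the ground-truth BED."""
    records = ground_truth.for_chromosome(chromosome)
    if not records:
        raise ValueError(f"no ground-truth records for {chromosome}")
    return min(r.start for r in records), max(r.end for r in records)


def run_pipeline(config: PipelineConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = setup_run_logging(outdir, config.log_level)
    logger.info("cenbarcode %s, seed %d, config %s", __version__, config.seed, config.config_hash())
    stages = set(config.stages)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": sorted(stages),
    }

    genome: list[SeqRecord] = []
    truth = GroundTruth()
    consensus_by_family = default_family_consensus()

    if "simulate" in stages:
        logger.info("simulate: %d-chromosome karyotype", config.n_chromosomes)
        specs = default_karyotype_specs(config.n_chromosomes)
        genome, truth = build_karyotype(
            specs,
            consensus_by_family=consensus_by_family,
            sub_rate=config.sub_rate,
            indel_rate=config.indel_rate,
            variant_divergence=config.variant_divergence,
            flank_frac=config.flank_frac,
            seed=config.seed,
        )
        write_fasta(genome, outdir / "genome.fa")
        write_bed(truth.to_bed(), outdir / "truth.bed")
        for library, rho, offset in (
            ("chip", config.enrichment_rho, 101),
            ("input", 1.0, 102),
        ):
            r1, r2 = simulate_reads(
                genome,
                truth,
                ReadSimConfig(
                    n_pairs=config.read_pairs,
                    enrichment=rho,
                    seed=config.seed + offset,
                ),
                library,
            )
            write_fastq(r1, outdir / f"{library}_R1.fastq")
            write_fastq(r2, outdir / f"{library}_R2.fastq")
        counts = simulate_qpcr_counts(DEFAULT_QPCR_FOLDS, seed=config.seed + 103)
        write_tsv(counts, outdir / "qpcr_counts.tsv")
        manifest["ground_truth_classes"] = {
            s.name: "/".join(str(k) for k in s.hor_classes) for s in specs
        }

    analyses: list[ArrayAnalysis] = []
    if "monomerize" in stages and genome:
        hit_intervals: list[IntervalRecord] = []
        consensus_records: list[SeqRecord] = []
        for rec in genome:
            start, end = array_span(truth, rec.id)
            analysis = analyze_array(
                rec.id,
                rec.sequence[start:end],
                period_range=config.period_range,
                min_identity=config.min_identity,
                cluster_identity_threshold=config.cluster_identity_threshold,
                hor_params=config.hor_params,
            )
            analyses.append(analysis)
            consensus_records.append(
                SeqRecord(id=f"{rec.id}_consensus", sequence=analysis.consensus)
            )
            for hit, symbol in zip(analysis.hits, analysis.symbols):
                hit_intervals.append(
                    IntervalRecord(
                        rec.id,
                        start + hit.start,
                        start + hit.end,
                        name="partial" if hit.partial else symbol,
                    )
                )
            logger.info(
                "%s: period %d bp, %d monomers, subfamily %s, HOR %s",
                rec.id,
                len(analysis.consensus),
                len(analysis.hits),
                analysis.subfamily,
                "/".join(c.hor_class for c in analysis.calls),
            )
        write_bed(hit_intervals, outdir / "hits.bed")
        write_fasta(consensus_records, outdir / "consensus.fa")

    if "hor" in stages and analyses:
        _, barcode_df = build_barcode(
            {a.chromosome: a.calls for a in analyses},
            {a.chromosome: a.subfamily for a in analyses},
        )
        write_tsv(barcode_df, outdir / "barcode.tsv")
        logger.info("hor: wrote %d barcode rows", len(barcode_df))

    if "phylo" in stages and analyses:
        monomers = []
        for analysis in analyses:
            full = [h for h in analysis.hits if not h.partial]
            n = min(config.n_monomers_sample, len(full))
            if n < 2:
                continue
            sampled = sample_monomers(
                analysis.hits, SamplingParams(n_per_chromosome=n, seed=config.seed)
            )
            monomers.extend(
                SeqRecord(id=f"{analysis.chromosome}.{i + 1}", sequence=h.sequence)
                for i, h in enumerate(sampled)
            )
        if len(monomers) >= 4:
            reference = analyses[0].consensus
            alignment = star_align(monomers, reference)
            tree, dropped = bootstrap_support(
                alignment,
                model="tn93",
                params=PhyloParams(
                    bootstrap_replicates=config.bootstrap_replicates,
                    seed=config.seed + 104,
                ),
            )
            tree.write(str(outdir / "tree.nwk"), format="newick")
            write_fasta(monomers, outdir / "sampled_monomers.fa")
            logger.info(
                "phylo: %d leaves, %d bootstrap replicates (%d dropped)",
                len(monomers),
                config.bootstrap_replicates,
                dropped,
            )

    if "enrich" in stages and (outdir / "chip_R1.fastq").exists():
        params = EnrichParams()
        chip = assign_reads(
            outdir / "chip_R1.fastq", outdir / "chip_R2.fastq", consensus_by_family, params
        )
        inp = assign_reads(
            outdir / "input_R1.fastq", outdir / "input_R2.fastq", consensus_by_family, params
        )
        table = enrichment_ratio(chip, inp, params)
        write_tsv(table, outdir / "enrichment.tsv")
        logger.info("enrich: %d families in table", len(table))

    if "qpcr" in stages and (outdir / "qpcr_counts.tsv").exists():
        counts = pd.read_csv(outdir / "qpcr_counts.tsv", sep="\t")
        write_tsv(qpcr_table(counts, QPCR_CONTROL), outdir / "qpcr.tsv")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if "report" in stages:
        make_report(outdir)
    logger.info("done: outputs in %s", outdir)
    return outdir


def make_report(outdir: str | Path) -> Path:
    """Render the markdown run report (idempotent, deterministic).

    One barcode row per chromosome plus enrichment and qPCR summaries;
    missing stage outputs are listed as absent.
    """
    outdir = Path(outdir)
    barcode_path = outdir / "barcode.tsv"
    if not barcode_path.exists():
        raise FileNotFoundError(f"{barcode_path} missing; run the hor stage first")
    lines = ["# Centromere barcode report", ""]

    barcode = pd.read_csv(barcode_path, sep="\t")
    lines.append("## Per-chromosome HOR barcodes")
    lines.append("")
    if barcode.empty:
        lines.append("no calls")
    else:
        lines.append("| chromosome | subfamily | HOR class | pattern | consistency | partials (bp) | two-variant |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, row in barcode.iterrows():
            partials = row["partial_lengths"] if pd.notna(row["partial_lengths"]) else ""
            lines.append(
                f"| {row['chromosome']} | {row['subfamily']} | {row['hor_class']} | "
                f"{row['unit_pattern']} | {row['consistency']} | {partials} | "
                f"{'*' if row['two_variant'] else ''} |"
            )
    lines.append("")

    enrichment_path = outdir / "enrichment.tsv"
    lines.append("## ChIP enrichment (ER = ChIP proportion / input proportion)")
    lines.append("")
    if enrichment_path.exists():
        table = pd.read_csv(enrichment_path, sep="\t")
        lines.append("| family | chip reads | input reads | ER | retained (ER > 2.0) |")
        lines.append("|---|---|---|---|---|")
        for _, row in table.iterrows():
            lines.append(
                f"| {row['family']} | {row['chip_count']} | {row['input_count']} | "
                f"{row['ER']:.2f} | {'yes' if row['retained'] else 'no'} |"
            )
    else:
        lines.append("absent (enrich stage skipped)")
    lines.append("")

    qpcr_path = outdir / "qpcr.tsv"
    lines.append("## qPCR relative enrichment (RE vs mock, t-test vs control)")
    lines.append("")
    if qpcr_path.exists():
        table = pd.read_csv(qpcr_path, sep="\t")
        lines.append("| target | mean RE | SE | p | significance |")
        lines.append("|---|---|---|---|---|")
        for _, row in table.iterrows():
            label = row["significance"] if pd.notna(row["significance"]) else ""
            lines.append(
                f"| {row['target']} | {row['mean_RE']:.2f} | {row['se_RE']:.2f} | "
                f"{row['p']:.3g} | {label} |"
            )
    else:
        lines.append("absent (qpcr stage skipped)")
    lines.append("")

    tree_path = outdir / "tree.nwk"
    lines.append("## Monomer phylogeny")
    lines.append("")
    if tree_path.exists():
        lines.append(f"Neighbor-joining tree with bootstrap supports: `{tree_path.name}`")
    else:
        lines.append("absent (phylo stage skipped)")
    lines.append("")

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
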