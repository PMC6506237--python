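"""End-to-end orchestration: simulate -> quantify -> call -> classify -> report.

The pipeline mirrors the study design at desk scale: a treated and a control
amplicon condition, a DNA on-target/indel condition, and a treated/control
mini-transcriptome pair that flows through pileup, Bayesian calling,
filtering, down-sampling spread estimation, average-frequency and bin-density
summaries, and consequence classification.  Identical config + seed gives an
identical output bundle; every reported number is computed by one module
operation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io, presets
from .amplicon import (
    align_reads_to_amplicon,
    indel_frequency,
    nucleotide_percentage_table,
    protospacer_editing,
    summarize_amplicon,
)
from .consequence import annotate_calls, consequence_summary, records_to_frame
from .models import EditingProfile, IndelSpec, QualityModel, SimConfig
from .simulate import (
    make_amplicon_reference,
    make_gene_models,
    simulate_amplicon_reads,
    simulate_transcriptome,
    uniform_transcriptome_profile,
)
from .transcriptome import (
    additional_edits,
    adenosine_sites,
    bin_edit_density,
    call_edits,
    filter_edit_calls,
    sem_by_repeated_downsampling,
    site_pileups,
    transcriptome_average_frequency,
)


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the study's printed values
    (detect threshold 0.1%, QUAL >= 20, coverage >= 20, 30-bp indel window,
    5-kb flanks, 1-Mb bins) at desk-scale simulation sizes."""

    seed: int = 0
    # amplicon stage
    amplicon_depth: int = 10_000
    amplicon_rate: float = presets.ABEMAX_RSL1D1_MEAN_RATE
    amplicon_control_rate: float = presets.CONTROL_RSL1D1_MEAN_RATE
    dna_on_target_rate: float = presets.DNA_ON_TARGET_RATE
    indel_rate: float = presets.INDEL_RATE
    mean_q: float = 30.0
    sd_q: float = 0.0
    # transcriptome stage
    n_transcripts: int = 30
    coverage: int = 60
    read_length: int = 100
    editor_site_fraction: float = 0.03
    editor_site_rate: float = 0.20
    endo_site_fraction: float = 0.01
    endo_site_rate: float = 0.30
    downsample_fraction: float = 0.5
    sem_reps: int = 5
    # thresholds (printed study parameters)
    detect_threshold: float = 0.001
    min_qual: float = 20.0
    min_coverage: int = 20
    indel_window: int = 30
    flank: int = 5000
    bin_size: int = 1_000_000
    # stage toggles
    run_amplicon: bool = True
    run_transcriptome: bool = True
    run_consequence: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.detect_threshold < 1.0:
            raise ValueError("detect_threshold must lie in (0, 1)")
        if self.min_qual < 0 or self.min_coverage < 0:
            raise ValueError("thresholds must be non-negative")
        if self.indel_window < 1 or self.flank < 0 or self.bin_size < 1:
            raise ValueError("window sizes must be positive")

    def to_flat(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_flat(cls, flat: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in flat:
                raw = flat[f.name]
                if f.type == "bool" or isinstance(f.default, bool):
                    kwargs[f.name] = str(raw).lower() in ("1", "true", "yes")
                elif isinstance(f.default, int) and not isinstance(f.default, bool):
                    kwargs[f.name] = int(raw)
                else:
                    kwargs[f.name] = float(raw)
        return cls(**kwargs)


def _amplicon_stage(config: PipelineConfig, qm: QualityModel,
                    seeds: np.ndarray, out: Path, report: dict) -> None:
    spec = presets.amplicon_stand_in("RSL1D1", seed=int(seeds[0]),
                                     molecule="cDNA")
    conditions = {
        "treated": presets.uniform_amplicon_profile(spec, config.amplicon_rate),
        "control": presets.uniform_amplicon_profile(
            spec, config.amplicon_control_rate, origin="endogenous"),
    }
    amp_report = {}
    for i, (label, profile) in enumerate(conditions.items()):
        cfg = SimConfig(depth=config.amplicon_depth, read_length=len(spec),
                        seed=int(seeds[1 + i]))
        reads, truth = simulate_amplicon_reads(spec, profile, qm, cfg)
        result = align_reads_to_amplicon(reads, spec)
        table = nucleotide_percentage_table(result, spec)
        summary = summarize_amplicon(table, spec, config.detect_threshold)
        io.write_tsv(table.to_frame(), out / f"amplicon_{label}_table.tsv",
                     index=True)
        truth.to_tsv(out / f"amplicon_{label}_truth.tsv")
        amp_report[label] = {
            "n_adenosines": summary.n_adenosines,
            "n_detectable": summary.n_detectable,
            "mean_a_to_i_percent": 100.0 * summary.mean_frequency,
            "n_reads": len(result),
            "n_discarded": result.n_discarded,
        }

    # DNA condition: on-target editing plus nick-window indels
    dna_spec = make_amplicon_reference(
        int(seeds[3]), length=240, target_a_protospacer_position=5,
        name="dna_on_target", molecule="DNA")
    dna_profile = presets.single_site_profile(dna_spec, 5,
                                              config.dna_on_target_rate)
    dna_cfg = SimConfig(depth=config.amplicon_depth,
                        read_length=len(dna_spec), seed=int(seeds[4]),
                        indel_rate=config.indel_rate,
                        indel_spec=IndelSpec(0, 2, "del"))
    dna_reads, dna_truth = simulate_amplicon_reads(dna_spec, dna_profile,
                                                   qm, dna_cfg)
    dna_result = align_reads_to_amplicon(dna_reads, dna_spec)
    dna_table = nucleotide_percentage_table(dna_result, dna_spec)
    pe = protospacer_editing(dna_table, dna_spec, target_position=5)
    amp_report["dna"] = {
        "on_target_percent": 100.0 * (pe.efficiency or 0.0),
        "indel_percent": 100.0 * indel_frequency(dna_result, dna_spec,
                                                 config.indel_window),
        "n_indel_reads_truth": dna_truth.n_indel_reads,
    }
    report["amplicon"] = amp_report


def _transcriptome_stage(config: PipelineConfig, qm: QualityModel,
                         seeds: np.ndarray, out: Path, report: dict) -> None:
    models = make_gene_models(int(seeds[5]), n_transcripts=config.n_transcripts)
    io.write_fasta(models.chromosomes, out / "genome.fa")
    io.write_gff3(models, out / "gene_models.gff3")
    sites = adenosine_sites(models)

    endo = uniform_transcriptome_profile(
        models, config.endo_site_rate, origin="endogenous",
        fraction=config.endo_site_fraction, seed=int(seeds[6]))
    endo_keys = {(e.chrom, e.position) for e in endo}
    editor_all = uniform_transcriptome_profile(
        models, config.editor_site_rate, origin="editor",
        fraction=config.editor_site_fraction, seed=int(seeds[7]))
    editor = EditingProfile(tuple(
        e for e in editor_all if (e.chrom, e.position) not in endo_keys))

    def run_condition(label: str, editor_profile: EditingProfile, seed: int):
        cfg = SimConfig(depth=config.coverage, read_length=config.read_length,
                        seed=seed)
        aln, truth = simulate_transcriptome(models, endo, editor_profile,
                                            qm, cfg)
        truth.to_tsv(out / f"transcriptome_{label}_truth.tsv")
        aln.to_sam(out / f"transcriptome_{label}.sam", models.chrom_lengths)
        pileups = site_pileups(aln, models.chromosomes, sites)
        calls = call_edits(pileups, min_qual=config.min_qual)
        kept = filter_edit_calls(calls, min_qual=config.min_qual)
        io.write_vcf(kept.kept, out / f"calls_{label}.vcf",
                     models.chrom_lengths)
        avg = transcriptome_average_frequency(
            pileups, min_coverage=config.min_coverage)
        return aln, pileups, kept, avg

    treated_aln, treated_pileups, treated_kept, treated_avg = run_condition(
        "treated", editor, int(seeds[8]))
    _, _, control_kept, control_avg = run_condition(
        "control", EditingProfile(()), int(seeds[9]))

    extra = additional_edits(treated_kept.kept, control_kept.kept, models)
    bins = bin_edit_density(treated_kept.kept, models.chrom_lengths,
                            config.bin_size)
    io.write_bed(bins, out / "bins_treated.bed")

    target_n = max(1, int(config.downsample_fraction * len(treated_aln)))

    def replicate_pipeline(subset):
        pl = site_pileups(subset, models.chromosomes, sites)
        return len(filter_edit_calls(call_edits(pl, min_qual=config.min_qual),
                                     min_qual=config.min_qual).kept)

    sem = sem_by_repeated_downsampling(
        treated_aln, target_n, config.sem_reps, int(seeds[10]),
        replicate_pipeline)

    report["transcriptome"] = {
        "n_adenosine_sites": len(sites),
        "n_high_confidence_treated": len(treated_kept.kept),
        "n_high_confidence_control": len(control_kept.kept),
        "additional_edits": extra.count_difference,
        "novel_transcripts": extra.n_novel_transcripts,
        "average_percent_treated": treated_avg,
        "average_percent_control": control_avg,
        "dropped_treated": treated_kept.dropped,
        "bin_count_total": int(bins["count"].sum()),
        "downsample_target": target_n,
        "sem_spread": sem.spread,
        "sem_values": sem.values,
    }

    if config.run_consequence:
        records = annotate_calls(treated_kept.kept, models, config.flank)
        io.write_tsv(records_to_frame(records), out / "consequences.tsv")
        if records:
            report["consequence"] = consequence_summary(records)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every enabled stage and write the report bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.default_rng(config.seed).integers(2 ** 31, size=16)
    qm = QualityModel(mean_q=config.mean_q, sd_q=config.sd_q,
                      max_q=max(41, round(config.mean_q)))
    report: dict = {"version": __version__, "seed": config.seed,
                    "parameters": config.to_flat()}

    if config.run_amplicon:
        _amplicon_stage(config, qm, seeds, out, report)
    if config.run_transcriptome:
        _transcriptome_stage(config, qm, seeds, out, report)

    io.write_config(config.to_flat(), out / "config_used.txt")
    io.write_json(report, out / "report.json")
    return report
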