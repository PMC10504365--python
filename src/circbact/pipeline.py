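"""End-to-end pipeline: simulate/load -> detect -> call -> annotate -> report.

One configuration object carries every threshold that affects output; the
run manifest records them all together with input digests and per-stage
record counts, so two runs with equal manifest inputs produce byte-identical
candidate outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .annotate import annotate_candidates
from .genome_io import (
    ReferenceSequence,
    read_fasta,
    read_fastq,
    read_gff3,
    write_bed6,
)
from .junctions import (
    candidates_to_frame,
    cluster_junctions,
    filter_candidates,
    tabulate_timecourse,
)
from .simulate import SimConfig, simulate
from .splitread import GenomeIndex, detect_backsplices


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every parameter of a pipeline run.

    Defaults equal the published extraction parameters: 30 nt windows with
    2 mismatches for locus scans, >= 5 junction reads, 1000 nt maximum span,
    1-3 nt junction clustering, 15 nt probe arms.
    """

    sim: Optional[SimConfig] = None
    genome_path: Optional[str] = None
    gff_path: Optional[str] = None
    reads_paths: dict = field(default_factory=dict)  # sample -> fastq path

    seed_k: int = 16
    min_anchor: int = 15
    max_span: int = 1000
    segment_mismatch: int = 2
    colinear_budget: Optional[int] = None
    cluster_shift: int = 3
    min_reads: int = 5
    require_unique: bool = True
    min_overlap_frac: float = 0.0
    probe_arm: int = 15

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim_raw = raw.pop("sim", None)
        sim = SimConfig(**sim_raw) if sim_raw is not None else None
        return cls(sim=sim, **raw)


@dataclass
class RunManifest:
    version: str
    parameters: dict
    inputs: dict
    seed: Optional[int]
    stage_counts: dict
    timestamp: str


@dataclass
class PipelineResult:
    candidates: list
    rejected: list
    evidence: list
    assignments: list
    truth: Optional[object]
    summary: dict
    manifest: RunManifest
    timecourse: Optional[object] = None


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir=None,
) -> PipelineResult:
    """Execute the full pipeline per ``config``; write outputs when ``outdir``.

    With ``config.sim`` set the inputs are generated in memory with planted
    truth; otherwise genome/annotation/reads are loaded from the configured
    paths.  Stage failures abort with the failing stage named and partial
    outputs removed.
    """
    stage = "setup"
    written: list = []
    try:
        truth = None
        inputs: dict = {}
        if config.sim is not None:
            stage = "simulate"
            sim_genome, truth, reads_by_sample = simulate(config.sim)
            genome = sim_genome.reference
            features = sim_genome.features
            inputs["sim_seed"] = config.sim.seed
        else:
            stage = "load"
            if not config.genome_path or not config.reads_paths:
                raise PipelineError("genome_path and reads_paths are required")
            genome = read_fasta(config.genome_path)[0]
            inputs["genome"] = _digest(config.genome_path)
            features = []
            if config.gff_path:
                features = read_gff3(config.gff_path)
                inputs["annotation"] = _digest(config.gff_path)
            reads_by_sample = {}
            for sample, path in config.reads_paths.items():
                reads_by_sample[sample] = list(read_fastq(path))
                inputs[f"reads_{sample}"] = _digest(path)

        stage = "detect"
        index = GenomeIndex(genome, k=min(config.seed_k, config.min_anchor))
        evidence = []
        stage_counts: dict = {"reads": {}, "colinear": {}, "evidence": {}}
        samples = sorted(reads_by_sample)
        for sample in samples:
            result = detect_backsplices(
                genome,
                reads_by_sample[sample],
                seed_k=config.seed_k,
                min_anchor=config.min_anchor,
                max_span=config.max_span,
                max_mismatch_per_segment=config.segment_mismatch,
                colinear_budget=config.colinear_budget,
                placement_tolerance=config.cluster_shift,
                sample=sample,
                index=index,
            )
            evidence.extend(result.evidence)
            stage_counts["reads"][sample] = result.stats["n_reads"]
            stage_counts["colinear"][sample] = result.stats["n_colinear"]
            stage_counts["evidence"][sample] = result.stats["n_evidence"]

        stage = "call"
        clusters = cluster_junctions(evidence, shift=config.cluster_shift)
        candidates, rejected = filter_candidates(
            clusters,
            min_reads=config.min_reads,
            max_span=config.max_span,
            require_unique=config.require_unique,
        )
        stage_counts["clusters"] = len(clusters)
        stage_counts["candidates"] = len(candidates)
        stage_counts["rejected"] = len(rejected)

        stage = "annotate"
        assignments = annotate_candidates(
            candidates, features,
            min_overlap_frac=config.min_overlap_frac,
            reference_length=len(genome),
        )

        stage = "report"
        timecourse = None
        if len(samples) > 1:
            timecourse = tabulate_timecourse(
                evidence, samples,
                shift=config.cluster_shift,
                min_reads=config.min_reads,
                max_span=config.max_span,
                require_unique=config.require_unique,
            )
        by_category: dict = {}
        for cand in candidates:
            if cand.rRNA_overlap:
                continue
            by_category[cand.category] = by_category.get(cand.category, 0) + 1
        summary = {
            "n_candidates": len(candidates),
            "n_excluded_rRNA": sum(1 for c in candidates if c.rRNA_overlap),
            "candidates_by_category": by_category,
            "per_sample": {
                s: {
                    "reads": stage_counts["reads"][s],
                    "colinear": stage_counts["colinear"][s],
                    "junction_evidence": stage_counts["evidence"][s],
                }
                for s in samples
            },
        }
        parameters = {
            k: v for k, v in asdict(config).items()
            if k not in ("sim", "genome_path", "gff_path", "reads_paths")
        }
        if config.sim is not None:
            parameters["sim"] = asdict(config.sim)
        manifest = RunManifest(
            version=__version__,
            parameters=parameters,
            inputs=inputs,
            seed=config.sim.seed if config.sim is not None else None,
            stage_counts=stage_counts,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

        if outdir is not None:
            stage = "write"
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)

            def _target(name):
                p = outdir / name
                written.append(p)
                return p

            frame = candidates_to_frame(candidates)
            frame.to_csv(_target("candidates.tsv"), sep="\t", index=False)
            bed_rows = [
                (
                    genome.name,
                    c.rep_acceptor_5p,
                    c.rep_donor_3p,
                    f"{c.rep_acceptor_5p}|{c.rep_donor_3p}|{c.read_count}",
                    c.read_count,
                    c.strand,
                )
                for cand in candidates
                for c in cand.isoforms
            ]
            write_bed6(bed_rows, _target("junctions.bed"))
            with open(_target("summary.json"), "w") as handle:
                json.dump(summary, handle, indent=2, sort_keys=True)
            with open(_target("manifest.json"), "w") as handle:
                json.dump(asdict(manifest), handle, indent=2, default=str)
            if timecourse is not None:
                timecourse.to_csv(_target("timecourse.tsv"), sep="\t")

        return PipelineResult(
            candidates=candidates,
            rejected=rejected,
            evidence=evidence,
            assignments=assignments,
            truth=truth,
            summary=summary,
            manifest=manifest,
            timecourse=timecourse,
        )
    except PipelineError:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
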