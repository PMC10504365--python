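"""Synthetic bacterial genome, mixed linear/circular transcriptome and reads.

The generator emulates the situation in which bacterial circular RNAs are
discovered: a small genome carrying linear transcripts plus circular RNA
loci whose junctions share a fixed 3' terminus and variable 5' termini, with
the circular fraction of the transcript pool rising across growth-phase
samples.  Circular transcripts are sampled from a rolling-circle template
(the circle sequence concatenated enough times to cover any fragment), so a
read may traverse the circularization junction.  Substitution sequencing
errors are applied i.i.d.; there are no indels — the downstream detector's
contract is Hamming-based.

Everything is reproducible bit-for-bit under a fixed seed, and the planted
truth (transcripts, junctions, realized per-sample junction-read counts and
per-read labels) is returned alongside the reads so recovery tests are
exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .genome_io import (
    FeatureRecord,
    ReferenceSequence,
    SequenceRead,
    reverse_complement,
    write_fasta,
    write_fastq,
    write_gff3,
)


class SimConfigError(ValueError):
    """Invalid or unsatisfiable simulation configuration."""


_DEFAULT_RAMP = (0.05, 0.15, 0.30, 0.50)


@dataclass
class SimConfig:
    """Parameters of one simulation.

    The circular-fraction ramp across samples emulates the growth-phase rise
    in the share of reads supporting circularization junctions; the default
    ramp ends with the circular form in the majority, as observed for
    late-phase DucS.  Defaults are set so planted circles always satisfy the
    downstream span filter (< 1000 nt) and exceed the read length (a read
    then crosses at most one junction).
    """

    genome_length: int = 50_000
    gc_fraction: float = 0.45
    n_linear_loci: int = 5
    n_circ_loci: int = 5
    linear_size_range: tuple = (300, 900)
    circ_size_range: tuple = (150, 500)
    n_samples: int = 4
    circ_fraction_by_sample: Optional[tuple] = None
    isoform_5prime_offsets: tuple = (35,)
    isoform_fraction: float = 0.2
    read_length: int = 100
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    coverage_per_sample: float = 80.0
    substitution_error_rate: float = 0.001
    rolling_circle: bool = True
    min_gap: int = 100
    seed: int = 20260921

    def __post_init__(self) -> None:
        if self.circ_fraction_by_sample is None:
            if self.n_samples == len(_DEFAULT_RAMP):
                self.circ_fraction_by_sample = _DEFAULT_RAMP
            elif self.n_samples == 1:
                self.circ_fraction_by_sample = (0.30,)
            else:
                lo, hi = _DEFAULT_RAMP[0], _DEFAULT_RAMP[-1]
                step = (hi - lo) / (self.n_samples - 1)
                self.circ_fraction_by_sample = tuple(
                    round(lo + i * step, 4) for i in range(self.n_samples)
                )
        self.validate()

    def validate(self) -> None:
        if self.genome_length <= 0 or self.n_samples <= 0:
            raise SimConfigError("genome_length and n_samples must be positive")
        if self.n_linear_loci < 0 or self.n_circ_loci < 0:
            raise SimConfigError("locus counts must be nonnegative")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise SimConfigError("gc_fraction must be in [0, 1]")
        if len(self.circ_fraction_by_sample) != self.n_samples:
            raise SimConfigError(
                "circ_fraction_by_sample must have one entry per sample"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.circ_fraction_by_sample):
            raise SimConfigError("circular fractions must be proportions in [0, 1]")
        if not 0.0 <= self.isoform_fraction <= 1.0:
            raise SimConfigError("isoform_fraction must be in [0, 1]")
        for lo, hi in (self.linear_size_range, self.circ_size_range):
            if lo < 1 or hi < lo:
                raise SimConfigError("size ranges must satisfy 1 <= min <= max")
        if self.read_length < 1:
            raise SimConfigError("read_length must be positive")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise SimConfigError("substitution_error_rate must be in [0, 1)")
        if self.linear_size_range[0] < self.read_length:
            raise SimConfigError(
                "linear loci must be at least one read long"
            )

    @property
    def sample_ids(self) -> list:
        return [f"s{i + 1}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class Locus:
    locus_id: str
    start: int
    end: int
    strand: str
    is_circular: bool
    context: Optional[str]  # gene | ncRNA | None (unannotated)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimGenome:
    reference: ReferenceSequence
    features: list
    loci: list


@dataclass(frozen=True)
class TranscriptTruth:
    locus_id: str
    tss: int
    tts: int
    strand: str
    is_circular: bool


@dataclass
class JunctionTruth:
    locus_id: str
    acceptor_5p: int
    donor_3p: int
    strand: str
    label: str
    counts: dict = field(default_factory=dict)  # sample -> realized junction reads

    @property
    def circle_length(self) -> int:
        return self.donor_3p - self.acceptor_5p + 1


@dataclass
class SimTruth:
    transcripts: list
    junctions: list
    reads_truth: dict = field(default_factory=dict)  # read_id -> (locus_id, spans)


_BASES = np.array(list("ACGT"))


def generate_genome(config: SimConfig) -> SimGenome:
    """I.i.d. genome at the configured GC plus non-overlapping annotated loci.

    Loci are separated by gaps of at least ``config.min_gap`` nt.  Linear
    loci are annotated as genes; circular loci cycle through gene / ncRNA /
    unannotated contexts so the downstream classifier sees every category;
    two rRNA features are placed in free gaps.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = "".join(rng.choice(_BASES, size=config.genome_length, p=probs))
    reference = ReferenceSequence(name="sim_chr", bases=bases)

    n = config.n_linear_loci + config.n_circ_loci
    sizes = []
    kinds = []
    for i in range(config.n_linear_loci):
        sizes.append(int(rng.integers(*config.linear_size_range, endpoint=True)))
        kinds.append(False)
    for i in range(config.n_circ_loci):
        sizes.append(int(rng.integers(*config.circ_size_range, endpoint=True)))
        kinds.append(True)
    order = rng.permutation(n)
    sizes = [sizes[i] for i in order]
    kinds = [kinds[i] for i in order]

    rrna_len = 120
    slack = (
        config.genome_length
        - sum(sizes)
        - config.min_gap * (n + 1)
        - 2 * (rrna_len + config.min_gap)
    )
    if slack < 0:
        raise SimConfigError(
            f"cannot place {n} loci plus rRNA features in a "
            f"{config.genome_length} nt genome with {config.min_gap} nt gaps"
        )
    extra = rng.multinomial(slack, np.ones(n + 1) / (n + 1)) if slack else [0] * (n + 1)

    loci = []
    circ_contexts = ["gene", "ncRNA", None]
    pos = 1
    lin_i = circ_i = 0
    free_gaps = []  # (gap_start, gap_end) usable for rRNA placement
    for i in range(n):
        gap = config.min_gap + int(extra[i])
        gap_start = pos
        pos += gap
        free_gaps.append((gap_start, pos - 1))
        start, end = pos, pos + sizes[i] - 1
        strand = "+" if i % 2 == 0 else "-"
        if kinds[i]:
            context = circ_contexts[circ_i % len(circ_contexts)]
            locus_id = f"circ_{circ_i + 1}"
            circ_i += 1
        else:
            context = "gene"
            locus_id = f"lin_{lin_i + 1}"
            lin_i += 1
        loci.append(Locus(locus_id, start, end, strand, kinds[i], context))
        pos = end + 1

    features = []
    for locus in loci:
        if locus.context is None:
            continue
        features.append(
            FeatureRecord(
                seq_name=reference.name,
                start=locus.start,
                end=locus.end,
                strand=locus.strand,
                feature_type=locus.context,
                attributes={"ID": f"{locus.context}_{locus.locus_id}"},
            )
        )
    # two rRNA features inside the widest free gaps, clear of every locus
    wide = sorted(free_gaps, key=lambda g: g[0] - g[1])[:2]
    for j, (gs, ge) in enumerate(sorted(wide)):
        if ge - gs + 1 < rrna_len + 2:
            continue
        start = gs + 1
        features.append(
            FeatureRecord(
                seq_name=reference.name,
                start=start,
                end=start + rrna_len - 1,
                strand="+",
                feature_type="rRNA",
                attributes={"ID": f"rRNA_{j + 1}"},
            )
        )
    features.sort(key=lambda f: f.start)
    return SimGenome(reference=reference, features=features, loci=loci)


def define_transcriptome(sim_genome: SimGenome, config: SimConfig) -> SimTruth:
    """Plant transcripts and circularization junctions on the placed loci.

    Every circular locus gets one primary junction spanning the whole locus
    plus one isoform per configured 5' offset; the 3' terminus (genomic
    right end on '+', left end on '-') is fixed across a locus's isoforms.
    """
    transcripts = []
    junctions = []
    for locus in sim_genome.loci:
        if locus.strand == "+":
            tss, tts = locus.start, locus.end
        else:
            tss, tts = locus.end, locus.start
        transcripts.append(
            TranscriptTruth(locus.locus_id, tss, tts, locus.strand, locus.is_circular)
        )
        if not locus.is_circular:
            continue
        junctions.append(
            JunctionTruth(locus.locus_id, locus.start, locus.end, locus.strand, "S1")
        )
        for off in config.isoform_5prime_offsets:
            if off >= locus.length:
                raise SimConfigError(
                    f"isoform offset {off} >= circle length {locus.length} "
                    f"at {locus.locus_id}"
                )
            if off == 0:
                continue
            if locus.strand == "+":
                a, d = locus.start + off, locus.end
            else:
                a, d = locus.start, locus.end - off
            junctions.append(
                JunctionTruth(locus.locus_id, a, d, locus.strand, f"S2+{off}")
            )
    return SimTruth(transcripts=transcripts, junctions=junctions)


def _apply_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return read
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    positions = rng.choice(len(read), size=n_err, replace=False)
    out = list(read)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[int(rng.integers(3))]
    return "".join(out)


def simulate_reads(
    truth: SimTruth, sim_genome: SimGenome, config: SimConfig
) -> dict:
    """Sample error-bearing single-end reads per sample; fill realized counts.

    Returns ``{sample_id: [SequenceRead, ...]}``; ``truth.reads_truth`` maps
    every read id to ``(locus_id, spans_junction)`` and every
    :class:`JunctionTruth` gets its realized per-sample junction-read count.
    Linear transcripts are sampled colinearly; circular transcripts from a
    rolling-circle template deep enough that fragments never run off it.
    """
    rng = np.random.default_rng(config.seed + 1)
    genome = sim_genome.reference
    loci = {l.locus_id: l for l in sim_genome.loci}
    linear = [t for t in truth.transcripts if not t.is_circular]
    circular = [t for t in truth.transcripts if t.is_circular]
    junctions_by_locus: dict = {}
    for j in truth.junctions:
        junctions_by_locus.setdefault(j.locus_id, []).append(j)
        for sample in config.sample_ids:
            j.counts.setdefault(sample, 0)

    for t in circular:
        locus = loci[t.locus_id]
        if config.read_length > locus.length and not config.rolling_circle:
            raise SimConfigError(
                f"read_length {config.read_length} > circle length "
                f"{locus.length} with rolling_circle disabled"
            )

    total_bases = sum(loci[t.locus_id].length for t in truth.transcripts)
    n_reads = int(round(config.coverage_per_sample * total_bases / config.read_length))
    lin_weights = np.array([loci[t.locus_id].length for t in linear], dtype=float)
    circ_weights = np.array([loci[t.locus_id].length for t in circular], dtype=float)
    if lin_weights.sum():
        lin_weights /= lin_weights.sum()
    if circ_weights.sum():
        circ_weights /= circ_weights.sum()

    reads_by_sample: dict = {}
    L = config.read_length
    for s_idx, sample in enumerate(config.sample_ids):
        circ_frac = config.circ_fraction_by_sample[s_idx]
        reads = []
        for i in range(n_reads):
            read_id = f"{sample}_r{i:06d}"
            draw_circ = bool(circular) and (
                not linear or rng.random() < circ_frac
            )
            if draw_circ:
                t = circular[int(rng.choice(len(circular), p=circ_weights))]
                locus = loci[t.locus_id]
                juncs = junctions_by_locus[t.locus_id]
                primary = juncs[0]
                isoforms = juncs[1:]
                if isoforms and rng.random() < config.isoform_fraction:
                    junc = isoforms[int(rng.integers(len(isoforms)))]
                else:
                    junc = primary
                circle = genome.slice(junc.acceptor_5p, junc.donor_3p)
                if locus.strand == "-":
                    circle = reverse_complement(circle)
                clen = len(circle)
                if config.rolling_circle:
                    copies = (
                        math.ceil(
                            (config.fragment_length_mean + 3 * config.fragment_length_sd)
                            / clen
                        )
                        + 1
                    )
                else:
                    copies = 2
                template = circle * copies
                start = int(rng.integers(clen))
                seq = template[start : start + L]
                spans = start + L > clen
                if spans:
                    junc.counts[sample] += 1
            else:
                t = linear[int(rng.choice(len(linear), p=lin_weights))]
                locus = loci[t.locus_id]
                tseq = genome.slice(locus.start, locus.end)
                if locus.strand == "-":
                    tseq = reverse_complement(tseq)
                frag = int(
                    np.clip(
                        round(rng.normal(config.fragment_length_mean,
                                         config.fragment_length_sd)),
                        L,
                        len(tseq),
                    )
                )
                start = int(rng.integers(len(tseq) - frag + 1))
                seq = tseq[start : start + L]
                spans = False
            seq = _apply_errors(seq, config.substitution_error_rate, rng)
            reads.append(SequenceRead(read_id=read_id, bases=seq, qualities="I" * len(seq)))
            truth.reads_truth[read_id] = (t.locus_id, spans)
        reads_by_sample[sample] = reads
    return reads_by_sample


def simulate(config: SimConfig) -> tuple:
    """Convenience wrapper: genome -> transcriptome -> reads.

    Returns ``(sim_genome, truth, reads_by_sample)``.
    """
    sim_genome = generate_genome(config)
    truth = define_transcriptome(sim_genome, config)
    reads = simulate_reads(truth, sim_genome, config)
    return sim_genome, truth, reads


def write_simulation(
    outdir, sim_genome: SimGenome, truth: SimTruth, reads_by_sample: dict,
    config: SimConfig,
) -> dict:
    """Write FASTQ per sample, genome FASTA, GFF3, truth TSV and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_fasta([sim_genome.reference], outdir / "genome.fasta")
    paths["genome"] = outdir / "genome.fasta"
    write_gff3(sim_genome.features, outdir / "annotation.gff3")
    paths["annotation"] = outdir / "annotation.gff3"
    for sample, reads in reads_by_sample.items():
        p = outdir / f"reads_{sample}.fastq"
        write_fastq(reads, p)
        paths[f"reads_{sample}"] = p
    with open(outdir / "truth.tsv", "w") as handle:
        handle.write("locus_id\tacceptor_5p\tdonor_3p\tstrand\tlabel\tsample\tjunction_reads\n")
        for j in truth.junctions:
            for sample in config.sample_ids:
                handle.write(
                    f"{j.locus_id}\t{j.acceptor_5p}\t{j.donor_3p}\t{j.strand}"
                    f"\t{j.label}\t{sample}\t{j.counts.get(sample, 0)}\n"
                )
    paths["truth"] = outdir / "truth.tsv"
    manifest = {"config": asdict(config)}
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)
    paths["manifest"] = outdir / "manifest.json"
    return paths
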