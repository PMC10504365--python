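"""Collapse per-read junction evidence into circRNA candidates.

Evidence records whose circularization points differ by a few nucleotides
(sequencing error, residual split ambiguity) describe the same junction;
they are merged by single-linkage clustering with a shift window of 3 nt on
both coordinates, the redundancy rule established for archaeal circular RNA
calling.  Clusters sharing a genomic interval form one locus, whose isoforms
are the alternative circularization junctions (fixed 3' terminus, variable
5' termini).  A locus becomes a candidate when its summed junction-read
support reaches the threshold (default >= 5), every isoform's genomic span
is within 1000 nt, and (optionally) placements are unique.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .splitread import PermutedReadEvidence


@dataclass
class JunctionCluster:
    """A collapsed junction with its supporting evidence."""

    rep_acceptor_5p: int
    rep_donor_3p: int
    strand: str
    read_count: int
    member_offsets: list
    samples: dict
    members: list = field(default_factory=list)
    chained: bool = False  # some member sits > shift from the representative

    @property
    def span(self) -> int:
        return self.rep_donor_3p - self.rep_acceptor_5p + 1

    @property
    def unique_placement(self) -> bool:
        """Majority vote over member uniqueness flags."""
        if not self.members:
            return False
        n_unique = sum(1 for m in self.members if m.unique_placement)
        return n_unique * 2 > len(self.members)

    @property
    def interval(self) -> tuple:
        lo = min(m.acceptor_5p for m in self.members)
        hi = max(m.donor_3p for m in self.members)
        return lo, hi


@dataclass
class CircCandidate:
    """A circRNA locus: one or more junction isoforms passing the filters."""

    locus_id: str
    isoforms: list
    total_reads: int
    span: int
    category: Optional[str] = None
    rRNA_overlap: bool = False
    unique_placement: bool = True

    @property
    def interval(self) -> tuple:
        lo = min(c.rep_acceptor_5p for c in self.isoforms)
        hi = max(c.rep_donor_3p for c in self.isoforms)
        return lo, hi


@dataclass(frozen=True)
class RejectedLocus:
    locus_id: str
    reason: str
    total_reads: int
    span: int


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_junctions(
    evidence: Iterable[PermutedReadEvidence], shift: int = 3
) -> list:
    """Single-linkage clustering of junction observations.

    Two observations join iff they share a strand and both coordinates
    differ by at most ``shift`` nt.  The representative is the modal
    (acceptor, donor) pair, ties broken toward smaller coordinates; the
    result is independent of input order and conserves evidence counts.
    """
    evidence = sorted(
        evidence,
        key=lambda e: (e.strand, e.acceptor_5p, e.donor_3p, e.read_id),
    )
    if not evidence:
        return []
    uf = _UnionFind(len(evidence))
    # evidence is sorted by (strand, acceptor): only nearby records can link
    for i, ei in enumerate(evidence):
        for j in range(i + 1, len(evidence)):
            ej = evidence[j]
            if ej.strand != ei.strand or ej.acceptor_5p - ei.acceptor_5p > shift:
                break
            if abs(ej.donor_3p - ei.donor_3p) <= shift:
                uf.union(i, j)
    groups: dict = defaultdict(list)
    for i in range(len(evidence)):
        groups[uf.find(i)].append(evidence[i])
    clusters = []
    for members in groups.values():
        counts = Counter((m.acceptor_5p, m.donor_3p) for m in members)
        top = max(counts.values())
        rep_a, rep_d = min(pair for pair, n in counts.items() if n == top)
        samples: dict = defaultdict(int)
        for m in members:
            samples[m.sample] += 1
        offsets = sorted((m.acceptor_5p - rep_a, m.donor_3p - rep_d) for m in members)
        chained = any(abs(da) > shift or abs(dd) > shift for da, dd in offsets)
        clusters.append(
            JunctionCluster(
                rep_acceptor_5p=rep_a,
                rep_donor_3p=rep_d,
                strand=members[0].strand,
                read_count=len(members),
                member_offsets=offsets,
                samples=dict(samples),
                members=members,
                chained=chained,
            )
        )
    clusters.sort(key=lambda c: (c.rep_acceptor_5p, c.rep_donor_3p, c.strand))
    return clusters


def group_loci(clusters: Iterable[JunctionCluster]) -> list:
    """Group clusters whose genomic intervals overlap into loci.

    Returns a list of cluster lists, sorted by genomic position.  Alternative
    circularization isoforms share the locus of their common region.
    """
    clusters = sorted(clusters, key=lambda c: (c.rep_acceptor_5p, c.rep_donor_3p))
    loci: list = []
    current: list = []
    current_end = -1
    for c in clusters:
        lo, hi = c.rep_acceptor_5p, c.rep_donor_3p
        if current and lo <= current_end:
            current.append(c)
            current_end = max(current_end, hi)
        else:
            if current:
                loci.append(current)
            current = [c]
            current_end = hi
    if current:
        loci.append(current)
    return loci


def filter_candidates(
    clusters: Iterable[JunctionCluster],
    min_reads: int = 5,
    max_span: int = 1000,
    require_unique: bool = True,
) -> tuple:
    """Apply the candidate filters; returns (retained, rejected).

    A locus is retained iff its summed junction reads reach ``min_reads``,
    every isoform's span is within ``max_span``, and — when required — every
    isoform's placement is unique (majority of members).  Rejected loci
    carry the first failing rule.
    """
    retained: list = []
    rejected: list = []
    for members in group_loci(clusters):
        lo = min(c.rep_acceptor_5p for c in members)
        hi = max(c.rep_donor_3p for c in members)
        locus_id = f"locus_{lo}_{hi}"
        total = sum(c.read_count for c in members)
        widest = max(c.span for c in members)
        reason = None
        if total < min_reads:
            reason = "min_reads"
        elif widest > max_span:
            reason = "max_span"
        elif require_unique and not all(c.unique_placement for c in members):
            reason = "non_unique"
        if reason is not None:
            rejected.append(
                RejectedLocus(locus_id=locus_id, reason=reason,
                              total_reads=total, span=widest)
            )
            continue
        retained.append(
            CircCandidate(
                locus_id=locus_id,
                isoforms=sorted(members, key=lambda c: -c.read_count),
                total_reads=total,
                span=widest,
                unique_placement=all(c.unique_placement for c in members),
            )
        )
    return retained, rejected


def junction_fractions(
    isoforms: Iterable[JunctionCluster],
    total_permuted: int,
    total_locus_reads: int,
) -> Optional[pd.Series]:
    """Per-junction percentages of all reads aligned to a locus.

    ``total_permuted`` counts every permuted read at the locus (isoform
    members plus any unclustered residue); ``total_locus_reads`` adds the
    colinear reads.  Returns percentages per isoform, an ``other_junctions``
    residue, and the colinear share; None when the locus has no reads
    (undefined, reported as missing rather than 0).
    """
    isoforms = list(isoforms)
    if total_locus_reads == 0:
        return None
    values = {}
    iso_total = 0
    for c in isoforms:
        label = f"{c.rep_acceptor_5p}-{c.rep_donor_3p}"
        values[label] = 100.0 * c.read_count / total_locus_reads
        iso_total += c.read_count
    values["other_junctions"] = 100.0 * (total_permuted - iso_total) / total_locus_reads
    values["colinear"] = 100.0 * (total_locus_reads - total_permuted) / total_locus_reads
    return pd.Series(values)


def tabulate_timecourse(
    evidence: Iterable[PermutedReadEvidence],
    samples: list,
    shift: int = 3,
    min_reads: int = 5,
    max_span: int = 1000,
    require_unique: bool = True,
) -> pd.DataFrame:
    """Per-sample candidate counts and per-locus junction-read counts.

    One row per sample: ``n_candidates`` is the number of loci passing the
    filters *within that sample*; the remaining columns give junction reads
    per locus (loci defined on the pooled evidence, counted at locus level —
    isoforms pooled).  Unknown sample ids raise ValueError.
    """
    evidence = list(evidence)
    known = set(samples)
    for e in evidence:
        if e.sample not in known:
            raise ValueError(f"unknown sample id {e.sample!r}")
    pooled = cluster_junctions(evidence, shift=shift)
    loci = group_loci(pooled)
    locus_ids = []
    locus_lookup = {}
    for members in loci:
        lo = min(c.rep_acceptor_5p for c in members)
        hi = max(c.rep_donor_3p for c in members)
        locus_id = f"locus_{lo}_{hi}"
        locus_ids.append(locus_id)
        for c in members:
            for m in c.members:
                locus_lookup[id(m)] = locus_id
    rows = []
    for sample in samples:
        sample_ev = [e for e in evidence if e.sample == sample]
        clusters = cluster_junctions(sample_ev, shift=shift)
        kept, _ = filter_candidates(
            clusters, min_reads=min_reads, max_span=max_span,
            require_unique=require_unique,
        )
        row = {"sample": sample, "n_candidates": len(kept)}
        counts = Counter(locus_lookup[id(e)] for e in sample_ev)
        for locus_id in locus_ids:
            row[locus_id] = counts.get(locus_id, 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def candidates_to_frame(candidates: Iterable[CircCandidate]) -> pd.DataFrame:
    """Flatten candidates (one row per isoform) for TSV output."""
    rows = []
    for cand in candidates:
        for c in cand.isoforms:
            rows.append(
                {
                    "locus_id": cand.locus_id,
                    "acceptor_5p": c.rep_acceptor_5p,
                    "donor_3p": c.rep_donor_3p,
                    "strand": c.strand,
                    "span": c.span,
                    "isoform_reads": c.read_count,
                    "locus_reads": cand.total_reads,
                    "category": cand.category or "",
                    "rRNA_overlap": cand.rRNA_overlap,
                    "unique_placement": cand.unique_placement,
                }
            )
    columns = ["locus_id", "acceptor_5p", "donor_3p", "strand", "span",
               "isoform_reads", "locus_reads", "category", "rRNA_overlap",
               "unique_placement"]
    return pd.DataFrame(rows, columns=columns)
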