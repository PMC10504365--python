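"""Genomic-context classification of circRNA candidates.

Candidates are placed into three categories against a GFF3 annotation:
``gene_region`` (overlapping a gene or CDS), ``known_ncRNA`` (no gene/CDS
overlap but overlapping an annotated noncoding RNA), and ``nonannotated``
(no overlap at all).  rRNA overlap does not categorize — rRNA is depleted
before sequencing, so apparent circles there are suspect — it sets an
exclusion flag and the candidate is reported but left out of headline
counts.  Overlap is strand-agnostic and requires one shared base by
default (``min_overlap_frac`` tightens this to a fraction of the candidate
interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .genome_io import FeatureRecord
from .junctions import CircCandidate

GENE_TYPES = frozenset({"gene", "CDS", "mRNA"})
NCRNA_TYPES = frozenset(
    {"ncRNA", "tRNA", "tmRNA", "SRP_RNA", "RNase_P_RNA", "riboswitch", "sRNA"}
)
RRNA_TYPES = frozenset({"rRNA"})

CATEGORIES = ("gene_region", "known_ncRNA", "nonannotated")


@dataclass(frozen=True)
class CategoryAssignment:
    locus_id: str
    category: str
    overlapping_features: tuple
    rRNA_overlap: bool


class FeatureIndex:
    """Interval index over annotation features for overlap queries."""

    def __init__(self, features: Iterable[FeatureRecord]):
        self._tree = IntervalTree()
        for feat in features:
            # IntervalTree is half-open; store [start, end + 1)
            self._tree[feat.start : feat.end + 1] = feat

    def overlapping(self, start: int, end: int, min_overlap_frac: float = 0.0):
        length = end - start + 1
        hits = []
        for iv in sorted(self._tree.overlap(start, end + 1)):
            feat = iv.data
            overlap = min(end, feat.end) - max(start, feat.start) + 1
            if overlap >= 1 and overlap / length >= min_overlap_frac:
                hits.append(feat)
        return hits


def classify_candidate(
    candidate: CircCandidate,
    features,
    min_overlap_frac: float = 0.0,
    reference_length: Optional[int] = None,
) -> CategoryAssignment:
    """Three-way category plus rRNA-exclusion flag for one candidate.

    Precedence: gene/CDS > ncRNA-class > nonannotated.  ``features`` may be
    a list of :class:`FeatureRecord` or a prebuilt :class:`FeatureIndex`.
    """
    start, end = candidate.interval
    if reference_length is not None and (start < 1 or end > reference_length):
        raise ValueError(
            f"candidate {candidate.locus_id} interval [{start}, {end}] "
            f"outside reference of length {reference_length}"
        )
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    hits = index.overlapping(start, end, min_overlap_frac)
    rrna = any(f.feature_type in RRNA_TYPES for f in hits)
    informative = [f for f in hits if f.feature_type not in RRNA_TYPES]
    if any(f.feature_type in GENE_TYPES for f in informative):
        category = "gene_region"
    elif any(f.feature_type in NCRNA_TYPES for f in informative):
        category = "known_ncRNA"
    else:
        category = "nonannotated"
    return CategoryAssignment(
        locus_id=candidate.locus_id,
        category=category,
        overlapping_features=tuple(hits),
        rRNA_overlap=rrna,
    )


def annotate_candidates(
    candidates: Iterable[CircCandidate],
    features,
    min_overlap_frac: float = 0.0,
    reference_length: Optional[int] = None,
) -> list:
    """Classify every candidate, writing category/flag back onto it."""
    features = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    assignments = []
    for cand in candidates:
        assignment = classify_candidate(
            cand, features, min_overlap_frac, reference_length
        )
        cand.category = assignment.category
        cand.rRNA_overlap = assignment.rRNA_overlap
        assignments.append(assignment)
    return assignments
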