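# Methods

## The problem and the model

Bacterial RNA-seq libraries occasionally contain reads that map to the
reference genome in *permuted, chiastic* order: the read's prefix aligns
downstream of its suffix. Such reads are the diagnostic signature of a
circularization (back-splice) junction — the covalent joint between a
transcript's 3' terminus (the **donor**, `donor_3p`) and an upstream 5'
terminus (the **acceptor**, `acceptor_5p`) — and are normally discarded by
colinear aligners. `circbact` detects these reads, collapses them into
junction clusters, filters the clusters into circRNA candidate loci,
classifies the loci by genomic context, and generates the in-silico
validation reagents (junction-spanning probes, divergent-primer virtual
PCR) that discriminate a circle from its linear precursor.

All coordinates are 1-based inclusive on the forward strand; a circle
closed between `acceptor` and `donor` has length `donor − acceptor + 1`
and a linear transcript `tts − tss + 1`. This inclusive convention is the
only one that reproduces all four published DucS sizes (232, 199, 200 and
165–174 nt) simultaneously, which the test suite asserts from the bundled
worked example (`circbact.coords.ducs_fixture`). For a minus-strand circle
the stored acceptor/donor are the genomic-left/right junction coordinates
(so `acceptor ≤ donor` always holds) and correspond to the transcript
3'/5' termini respectively.

## Detection cascade

Matching is ungapped and Hamming-based throughout — the locus-scan
procedure this package re-implements tolerates substitutions only — and an
`N` base never counts as a match.

1. **Colinear triage** (`align_full`). Each read is first offered a
   contiguous full-length placement on either strand within a mismatch
   budget (default `max(2, read_length // 20)`). Candidate offsets come
   from a pigeonhole block filter: a placement with ≤ *b* mismatches must
   match one of *b* + 1 disjoint read blocks exactly, so the filter is
   exhaustive-equivalent at any budget. Colinearly placeable reads never
   produce junction evidence — the detector operates on the unmappable
   remainder, matching the order of operations of a standard RNA-seq
   workflow.
2. **Seeding and extension** (`seed_segments`). Exact k-mer seeds
   (default k = 16, reduced to `min(k, min_anchor)` at call sites) are
   looked up in a genome hash index and extended ungapped in both
   directions while cumulative mismatches stay within a per-segment budget
   (default 2); maximal segments are deduplicated per diagonal.
3. **Chiastic pairing** (`call_backsplice`). A junction requires a prefix
   segment (anchored at read position 0) and a suffix segment (reaching
   the read end) on the same strand, the prefix placed strictly downstream
   of the suffix, a compatible split point, anchors of at least
   `min_anchor` nt on each side (default 15 nt, the length a
   junction-spanning probe covers per side), and a genomic span within
   `[2·min_anchor, max_span]` with `max_span` = 1000 nt.
4. **Canonicalization.** When flanking homology lets the split point
   slide, the junction is shifted to its leftmost sequence-equivalent
   coordinates (circle length is invariant under the shift; the operation
   is idempotent). Any consistent convention would do; leftmost is chosen
   for determinism.
5. **Uniqueness.** A read's placement is called unique iff all its
   *best-scoring* canonical candidate junctions lie within the cluster
   shift tolerance (3 nt) of each other. Strictly worse-scoring split
   variants — produced by sequencing errors or junction homology — are not
   counted as alternative placements; an equally good placement elsewhere
   in the genome is. Paired mates contribute at most one evidence record
   per fragment (the better-supported mate).

### Exhaustive-equivalence guarantee

The colinear stage is provably equivalent to exhaustive search at any
budget. The seeded junction path is provably equivalent to brute-force
enumeration of all split points, offsets and strands when run in
*exact-anchor mode* (per-segment mismatch budget 0, seed length ≤
`min_anchor`): every exact anchor of length ≥ `min_anchor` then contains
its own seed. With a nonzero per-segment budget the greedy extension is a
sensitive heuristic — a two-mismatch placement of a short anchor need not
contain an exact seed — which is the standard trade-off in split-read
callers; that mode is validated against planted ground truth rather than
by enumeration. The test suite checks exact-mode equivalence on 100 seeded
instances (2 kb genomes, 80 nt reads) against an independently written
brute-force oracle.

## Clustering and filters

Junction observations whose circularization points differ by at most 3 nt
on both coordinates (same strand) are merged by single-linkage clustering;
the representative is the modal (acceptor, donor) pair with ties broken
toward smaller coordinates, so the result is independent of input order
and conserves evidence counts. Single-linkage can in principle chain
beyond 3 nt in pathologically dense evidence; members sitting further than
the shift window from the representative set a `chained` flag rather than
being split, since the published rule is stated pairwise.

Clusters whose genomic intervals overlap share a locus (alternative
circularization isoforms: fixed 3' terminus, variable 5' termini). A locus
becomes a candidate iff its summed junction reads reach `min_reads`
(default 5 — the "at least five junction reads" reading; the alternative
"more than 5" reading is one flag away), every isoform's span is ≤ 1000
nt, and, when required, every isoform's placement is unique (majority vote
over members). Rejected loci are reported with the first failing rule.
Filtering is monotone in `min_reads` by construction.

Per-locus junction fractions are percentages of *all* reads aligned to
the locus (permuted + colinear), with residual permuted reads reported as
"other junctions"; a locus with zero reads reports missing values rather
than 0. The time-course table counts candidates per sample at locus level
(isoforms pooled), with loci defined on the pooled evidence.

## Annotation

Candidates are classified against the annotation with precedence
gene/CDS > ncRNA-class (`ncRNA, tRNA, tmRNA, SRP_RNA, RNase_P_RNA,
riboswitch, sRNA` — a documented, configurable vocabulary) >
nonannotated. Overlap is strand-agnostic (library strandedness is often
unknown) and requires ≥ 1 shared base by default; `min_overlap_frac`
tightens it. rRNA overlap never categorizes — rRNA is depleted before
sequencing, so circles there are suspect — it sets an exclusion flag and
the candidate is left out of headline counts.

## Assay design

The junction probe is the reverse complement of the 2·arm-nt sequence a
junction-spanning read traverses (arm = 15 nt per side by default); it
full-length-matches only templates that traverse the junction. Virtual
PCR is exact-match by default (the artifact validates junction logic, not
oligo thermodynamics): circular templates are searched as the sequence
concatenated to itself enough times to cover the amplicon bound, so
rolling-circle ladders (base length plus multiples of the circle length)
are reported. For any circle, a divergent pair drawn from within it yields
no product on the linear template and at least one on the circular one;
the convergent pair amplifies both — the discrimination logic used for
wet-lab validation.

## Synthetic data: what it emulates and what it does not

The generator plants a small i.i.d. genome (default 50 kb, GC 0.45) with
non-overlapping loci separated by ≥ 100 nt: 5 linear loci (300–900 nt,
annotated as genes) and 5 circular loci (150–500 nt) cycling through
gene / ncRNA / unannotated contexts, plus two standalone rRNA features, so
the classifier sees every category. Each circular locus carries a primary
junction spanning the locus plus isoforms at configured 5' offsets
(default 35 nt, drawn by 20% of that locus's circular reads — a fixed 3'
terminus with a minority shorter-5' isoform, the observed DucS pattern).

Reads (single-end, default 100 nt, fragment 250 ± 30 nt) are sampled
colinearly from linear transcripts and from rolling-circle templates for
circular ones (`ceil((fragment_mean + 3·sd)/circle_length) + 1` copies, so
fragments never run off the template); a read starting within the first
circle copy spans the junction iff it crosses a copy boundary, giving the
closed-form single-pass spanning probability `(read_length − 1) /
circle_length` that the tests check. Substitution errors are i.i.d.
(default 0.1%, a typical short-read scale); there are no indels, quality
models, PCR duplicates or strand-specific protocols. The circular fraction
ramps across 4 samples as (0.05, 0.15, 0.30, 0.50), emulating the
growth-phase rise of circular forms to late-phase dominance; coverage
(default 80× over transcribed bases) and ramp spacing were chosen together
so that expected per-circle junction-read counts per sample (≈ 11, 34,
68, 113) are separated by ≥ 3 Poisson standard deviations — the planted
monotone trend is then not masked by counting noise. Truth records
*realized* post-sampling junction-read counts, not expectations, so
recovery tests are exact.

Consequently, passing tests demonstrate correctness of the junction
calculus, the filters and the bookkeeping under substitution noise and
known abundance structure; they say nothing about indel robustness,
adapter contamination, coverage biases or rRNA depletion artifacts in
real libraries.

## Numerical and design choices

- Desk-scale problem sizes throughout (50 kb genomes, tens of thousands of
  reads): the detector is pure Python over hash indexes and string
  primitives, chosen for auditability over throughput.
- Reads crossing a junction more than once (read longer than the circle)
  are not callable by the prefix/suffix split model and are excluded by
  the simulator defaults (minimum circle 150 nt > read 100 nt).
- The genome is treated as a linear string; junctions wrapping the
  replication origin of a circular chromosome are out of scope.
- Same-strand constraint on the two segments: a back-splice joins ends of
  one transcript; inter-strand chimeras are discarded as artifacts.
- Degenerate inputs: empty read sets produce valid empty outputs; a zero
  denominator in junction fractions reports missing, not 0; tie-breaks
  (modal representative, leftmost shift, smaller coordinates first) are
  all deterministic, and the pipeline is byte-reproducible under a fixed
  seed and configuration.

## Known limitations

Substitution-only error model; no gapped or spliced alignment; no
FM-index-scale performance; uniqueness is assessed within the candidate
enumeration (genome-wide) with a single flag rather than separate
genome-wide/within-span checks; no statistical model of junction counts —
the filters are the published hard thresholds, and differential
circularization testing between conditions is out of scope.
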