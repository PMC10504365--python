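# circbact

Circular-RNA discovery in bacterial RNA-seq from *permuted reads* — reads
whose prefix maps downstream of their suffix on the genome, the diagnostic
signature of a circularization (back-splice) junction. `circbact` is a
desk-scale, fully testable re-implementation of that computation for people
studying bacterial sRNA circularization: it detects permuted reads, calls
and filters junction candidates, classifies them by genomic context,
handles the transcript/junction coordinate arithmetic, and designs the
probes and primers used to validate circles — with a synthetic-data
generator that plants ground truth so every stage can be verified exactly.

## The model

A circle closed between an acceptor (5' terminus) and a donor (3'
terminus) has length

    len_circ = donor_3p − acceptor_5p + 1        (1-based, inclusive)

and a linear transcript `len_lin = tts − tss + 1`. A junction-spanning read
traverses `donor`-side then `acceptor`-side sequence; detection therefore
looks for reads that fail colinear placement but decompose into a prefix
segment strictly downstream of a suffix segment (same strand, ≥ 15 nt
anchor on each side, genomic span ≤ 1000 nt). Per-read observations whose
circularization points differ by ≤ 3 nt collapse into one junction; a locus
is a candidate when its junctions collect ≥ 5 supporting reads. Candidates
are categorized as gene region / known ncRNA / nonannotated, with rRNA
overlap flagged and excluded from headline counts. See `docs/methods.md`
for the full model, parameter table and limitations.

## Worked example

`examples/02_simulate_and_detect.py` plants 3 circular and 3 linear loci
in a 20 kb genome (each circle has a primary junction plus a shorter-5'
isoform), then recovers them from the raw reads:

```
planted junctions (canonical coordinates may shift left by homology):
  circ_1   S1     2384-2583 (+) 25 spanning reads
  circ_1   S2+35  2419-2583 (+) 6 spanning reads
  ...
called candidates:
         locus_id  acceptor_5p  donor_3p strand  span  isoform_reads  locus_reads     category
  locus_2384_2583         2384      2583      +   200             20           25  gene_region
  locus_2384_2583         2419      2583      +   165              5           25  gene_region
  locus_8123_8300         8123      8300      +   178             24           29  known_ncRNA
  ...
1168 reads -> 1070 colinear, 83 junction evidence records, 3 candidate loci
```

Every called junction matches a planted one (the minus-strand locus is
reported at its leftmost sequence-equivalent coordinates), each circle's
primary and isoform junctions are resolved separately, and the three loci
land in the three annotation categories.

The bundled DucS worked example (`examples/01_ducs_coordinates.py`,
`circbact ducs-demo`) computes, from published coordinates alone, the
transcript sizes 232 and 199 nt and circle sizes 200 and 165–174 nt:

```
   label     form  start    end  length_nt
      L1   linear 946314 946545        232
      L2   linear 946314 946512        199
 C1 (S1) circular 946314 946513        200
 C2 (S2+35) ...                        165
```

`examples/03_assay_design.py` shows the validation logic for a planted
circle — the 30-nt junction probe matches the doubled circle but not the
linear genome, and divergent primers amplify only the circular template,
as a rolling-circle ladder:

```
divergent PCR: linear template -> [], circular template -> [60, 260, 460, 660, 860]
```

## Command line

A thin CLI mirrors the library: `circbact simulate | scan-locus | detect |
call | annotate | timecourse | design | vpcr | ducs-demo | run`. For
example, `circbact run --outdir out` simulates with defaults, detects,
calls, annotates and writes `candidates.tsv`, `junctions.bed`,
`summary.json`, `timecourse.tsv` and a run manifest recording every
effective parameter.

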