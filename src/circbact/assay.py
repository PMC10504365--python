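"""In-silico validation reagents: junction-spanning probes and virtual PCR.

A circular RNA is discriminated from its linear precursor by two designs:
a probe complementary to a fixed number of nucleotides on each side of the
circularization junction (hybridizes to the circle only — the linear
molecule never carries the joined sequence), and a divergent primer pair,
pointing away from each other on the linear sequence, which can only yield
a product when the template is circular (or a rolling-circle concatemer).
Primer binding is exact-match by default: this module validates junction
logic, not oligo thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .coords import CircleJunction, circle_length, junction_sequence
from .genome_io import ReferenceSequence, reverse_complement

MIN_PRIMER_LEN = 15


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers with their intended orientation."""

    forward: str
    reverse: str
    orientation: str  # convergent | divergent

    def __post_init__(self) -> None:
        if len(self.forward) < MIN_PRIMER_LEN or len(self.reverse) < MIN_PRIMER_LEN:
            raise ValueError(f"primers must be >= {MIN_PRIMER_LEN} nt")
        if self.orientation not in ("convergent", "divergent"):
            raise ValueError("orientation must be convergent or divergent")


def design_junction_probe(genome, junction: CircleJunction, arm: int = 15) -> str:
    """Probe complementary to ``arm`` nt on each side of the junction.

    The reverse complement of the junction-spanning sequence; length
    ``2 * arm``.  It full-length-matches only templates that traverse the
    junction (the circle, or a concatemer of it), never the linear genome.
    """
    return reverse_complement(junction_sequence(genome, junction, arm))


def _binding_sites(template: str, probe: str, max_mismatch: int = 0) -> list:
    """0-based start offsets where ``probe`` matches within the budget."""
    if max_mismatch == 0:
        sites = []
        pos = template.find(probe)
        while pos != -1:
            sites.append(pos)
            pos = template.find(probe, pos + 1)
        return sites
    sites = []
    p = len(probe)
    for off in range(len(template) - p + 1):
        mm = 0
        for x, y in zip(probe, template[off : off + p]):
            if x != y or x == "N":
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            sites.append(off)
    return sites


def virtual_pcr(
    template: str,
    circular: bool,
    pair: PrimerPair,
    max_amplicon: int = 2000,
    max_mismatch: int = 0,
) -> list:
    """Amplicon lengths produced by the pair on the template.

    The forward primer binds the template as written; the reverse primer
    binds where its reverse complement occurs.  A product requires the
    forward site upstream of the reverse site and a length within
    ``max_amplicon``.  Circular templates are searched as the sequence
    concatenated to itself enough times to cover ``max_amplicon``, so
    rolling-circle series (base length plus multiples of the circle length)
    are reported; forward sites are restricted to the first copy to avoid
    double counting.  An empty list means no product.
    """
    if not template:
        return []
    n = len(template)
    search = template
    fwd_limit = n
    if circular:
        copies = max_amplicon // n + 2
        search = template * copies
    fwd_sites = [s for s in _binding_sites(search, pair.forward, max_mismatch)
                 if s < fwd_limit]
    rev_rc = reverse_complement(pair.reverse)
    rev_sites = _binding_sites(search, rev_rc, max_mismatch)
    lengths = set()
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_rc)
            if r < f:
                continue
            length = end - f
            if length <= max_amplicon:
                lengths.add(length)
    return sorted(lengths)


def suggest_primers(
    genome,
    junction: CircleJunction,
    primer_len: int = 20,
    margin: int = 10,
) -> dict:
    """Convergent and divergent primer pairs drawn from within the circle.

    The divergent pair binds near the circle's termini pointing outward on
    the linear sequence: productive only across the junction, i.e. on a
    circular template.  The convergent pair brackets the interior as a
    positive control.  Requires a circle long enough to hold two primers
    plus margins without overlap.
    """
    bases = genome.bases if isinstance(genome, ReferenceSequence) else genome
    clen = circle_length(junction)
    if clen < 2 * (primer_len + margin) + 2:
        raise ValueError(
            f"circle of {clen} nt too short for {primer_len} nt primers "
            f"with {margin} nt margins"
        )
    circle = bases[junction.acceptor_5p - 1 : junction.donor_3p]
    fwd_conv = circle[margin : margin + primer_len]
    rev_conv = reverse_complement(circle[clen - margin - primer_len : clen - margin])
    fwd_div = circle[clen - margin - primer_len : clen - margin]
    rev_div = reverse_complement(circle[margin : margin + primer_len])
    return {
        "convergent": PrimerPair(fwd_conv, rev_conv, "convergent"),
        "divergent": PrimerPair(fwd_div, rev_div, "divergent"),
        "circle": circle,
    }
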