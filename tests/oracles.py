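"""Independent brute-force oracles used to check the seeded implementations.

Everything here is deliberately naive — exhaustive loops over offsets, split
points and strands — and shares no code with the package's detection path
(reverse complementation comes from Biopython).
"""

from __future__ import annotations

from Bio.Seq import Seq


def rc(s: str) -> str:
    return str(Seq(s).reverse_complement())


def ham(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def best_colinear(read: str, genome: str, budget: int):
    """Exhaustive best full-read ungapped placement: (mm, strand, offset_0b)."""
    best = None
    L = len(read)
    for strand, seq in (("+", read), ("-", rc(read))):
        for off in range(len(genome) - L + 1):
            mm = ham(seq, genome[off : off + L])
            if mm <= budget:
                key = (mm, 0 if strand == "+" else 1, off)
                if best is None or key < best:
                    best = key
    return best


def _exact_sites(piece: str, genome: str):
    sites = []
    pos = genome.find(piece)
    while pos != -1:
        sites.append(pos)
        pos = genome.find(piece, pos + 1)
    return sites


def _sites(piece: str, genome: str, budget: int):
    if budget == 0:
        return _exact_sites(piece, genome)
    n = len(piece)
    return [
        off
        for off in range(len(genome) - n + 1)
        if ham(piece, genome[off : off + n]) <= budget
    ]


def left_shift(acceptor: int, donor: int, genome: str):
    """Leftmost sequence-equivalent junction coordinates (1-based)."""
    a, d = acceptor, donor
    while a > 1 and genome[a - 2] == genome[d - 1] and genome[a - 2] != "N":
        a -= 1
        d -= 1
    return a, d


def brute_force_backsplices(
    read: str,
    genome: str,
    max_span: int = 1000,
    min_anchor: int = 15,
    per_side_budget: int = 0,
):
    """All canonical chiastic junctions over every split point, offset, strand.

    Returns a set of (strand, acceptor_1b, donor_1b) canonical keys.
    """
    out = set()
    L = len(read)
    for strand, seq in (("+", read), ("-", rc(read))):
        for s in range(min_anchor, L - min_anchor + 1):
            pref, suff = seq[:s], seq[s:]
            pref_sites = _sites(pref, genome, per_side_budget)
            if not pref_sites:
                continue
            for q in _sites(suff, genome, per_side_budget):
                acceptor = q + 1
                for p in pref_sites:
                    donor = p + s  # 1-based inclusive end of the prefix
                    span = donor - acceptor + 1
                    if 2 * min_anchor <= span <= max_span and acceptor < donor:
                        out.add((strand,) + left_shift(acceptor, donor, genome))
    return out


def brute_force_window_matches(
    windows, reads, max_mismatch: int = 2
):
    """All (window_start, read_id, read_offset, strand, mm) by direct loops."""
    out = set()
    for win in windows:
        w = len(win.bases)
        for read in reads:
            for strand in ("+", "-"):
                seq = read.bases if strand == "+" else rc(read.bases)
                for off in range(len(seq) - w + 1):
                    mm = ham(win.bases, seq[off : off + w])
                    if mm <= max_mismatch:
                        read_off = off if strand == "+" else len(seq) - w - off
                        out.add((win.start, read.read_id, read_off, strand, mm))
    return out
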