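"""Transcript and circularization-junction coordinate arithmetic.

A bacterial locus that circularizes produces two coordinate systems worth of
bookkeeping: the linear precursor, bounded by a transcription start site
(TSS) and one or more termination sites (TTS), and the circle itself, whose
back-splice junction joins a fixed 3' terminus (donor) to a variable 5'
terminus (acceptor).  All arithmetic here is 1-based inclusive, so a
transcript from position ``tss`` to ``tts`` has length ``tts - tss + 1`` and
a circle closed between ``acceptor`` and ``donor`` has length
``donor - acceptor + 1`` — the only convention consistent with the published
DucS sizes, which the bundled worked example reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import ReferenceSequence


@dataclass(frozen=True)
class TranscriptBoundary:
    """TSS plus the (possibly multiple) termination sites of a linear RNA."""

    tss: int
    tts_list: tuple
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand == "+" and any(t < self.tss for t in self.tts_list):
            raise ValueError("on the + strand every TTS must be >= TSS")


@dataclass(frozen=True)
class CircleJunction:
    """Back-splice junction: circle 5' terminus (acceptor) and 3' terminus (donor)."""

    acceptor_5p: int
    donor_3p: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.acceptor_5p > self.donor_3p:
            raise ValueError(
                f"junction {self.label or '?'}: acceptor_5p "
                f"{self.acceptor_5p} > donor_3p {self.donor_3p}"
            )


def linear_length(tss: int, tts: int) -> int:
    """Length in nt of a linear transcript from ``tss`` to ``tts`` inclusive."""
    if tts < tss:
        raise ValueError(f"tts {tts} < tss {tss}: wrong orientation")
    return tts - tss + 1


def circle_length(junction: CircleJunction) -> int:
    """Length in nt of the circle closed by ``junction`` (inclusive ends)."""
    return junction.donor_3p - junction.acceptor_5p + 1


def junction_sequence(genome, junction: CircleJunction, arm: int = 15) -> str:
    """The sequence a junction-spanning read traverses.

    ``arm`` nt ending at the donor (circle 3' end) followed by ``arm`` nt
    starting at the acceptor (circle 5' end); total length ``2 * arm``.
    """
    bases = genome.bases if isinstance(genome, ReferenceSequence) else genome
    clen = circle_length(junction)
    if arm < 1:
        raise ValueError("arm must be >= 1")
    if 2 * arm > clen:
        raise ValueError(f"arm {arm} exceeds half the circle length {clen}")
    a, d = junction.acceptor_5p, junction.donor_3p
    donor_side = bases[d - arm : d]
    acceptor_side = bases[a - 1 : a - 1 + arm]
    return donor_side + acceptor_side


@dataclass(frozen=True)
class DucsFixture:
    """The DucS sRNA worked example: published coordinates, no sequence.

    DucS of *Bacillus altitudinis* transcribes from a single TSS with two
    termination sites, giving linear forms L1 (longest) and L2, and
    circularizes with a fixed 3' terminus one base past the first TTS.  The
    major junction (S1) closes at the TSS; the minor junction family (S2)
    closes 26-35 nt downstream of the TSS (offsets counted inclusively from
    the TSS base, the reading that reproduces the published 165-174 nt
    circle sizes).
    """

    boundary: TranscriptBoundary
    s1: CircleJunction
    s2_offsets: tuple
    donor_3p: int

    @property
    def s2_junctions(self) -> list:
        return [
            CircleJunction(self.boundary.tss + off, self.donor_3p, label=f"S2+{off}")
            for off in self.s2_offsets
        ]

    def table(self) -> pd.DataFrame:
        """Label / coordinates / computed length for every DucS form."""
        tss = self.boundary.tss
        tts1, tts2 = self.boundary.tts_list
        rows = [
            ("L1", "linear", tss, tts2, linear_length(tss, tts2)),
            ("L2", "linear", tss, tts1, linear_length(tss, tts1)),
            ("C1 (S1)", "circular", self.s1.acceptor_5p, self.s1.donor_3p,
             circle_length(self.s1)),
        ]
        for junc in self.s2_junctions:
            rows.append(
                ("C2 (%s)" % junc.label, "circular", junc.acceptor_5p,
                 junc.donor_3p, circle_length(junc))
            )
        return pd.DataFrame(
            rows, columns=["label", "form", "start", "end", "length_nt"]
        )


def ducs_fixture() -> DucsFixture:
    """Published DucS coordinates as a ready-made worked example."""
    tss = 946314
    tts_1st = 946512
    tts_2nd = 946545
    donor = 946513  # fixed circle 3' terminus, one base past TTS_1st
    return DucsFixture(
        boundary=TranscriptBoundary(tss=tss, tts_list=(tts_1st, tts_2nd)),
        s1=CircleJunction(tss, donor, label="S1"),
        s2_offsets=tuple(range(26, 36)),
        donor_3p=donor,
    )
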