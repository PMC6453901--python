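"""Longest-ORF extraction for contigs lacking curated gene predictions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

#: frames scanned in tie-break order: forward +1,+2,+3 then reverse -1,-2,-3
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class Orf:
    protein: str
    frame: int
    #: 0-based [start, end) nucleotide coordinates on the input strand
    nt_start: int
    nt_end: int


def longest_orf(sequence: str, min_aa: int = 30) -> Optional[Orf]:
    """Longest ATG-initiated, stop-terminated ORF over all six frames.

    Ties break by frame order (forward frames first) then by the 5'-most
    start within the frame. Returns ``None`` when no ORF reaches ``min_aa``
    amino acids (stop codon excluded). Ns translate to X and cannot form a
    start or stop codon.
    """
    seq = Seq(sequence.upper())
    n = len(seq)
    best: Optional[Orf] = None
    for frame in FRAMES:
        strand = seq if frame > 0 else seq.reverse_complement()
        off = abs(frame) - 1
        trimmed = strand[off : off + ((n - off) // 3) * 3]
        prot = str(trimmed.translate())
        # scan for M...* runs, 5'-most start first
        start = 0
        while True:
            m = prot.find("M", start)
            if m == -1:
                break
            stop = prot.find("*", m)
            if stop == -1:
                break  # unterminated; later starts in this frame are shorter
            length = stop - m
            if length >= min_aa and (best is None or length > len(best.protein)):
                a, b = off + 3 * m, off + 3 * (stop + 1)
                if frame < 0:  # map back to input-strand coordinates
                    a, b = n - b, n - a
                best = Orf(protein=prot[m:stop], frame=frame, nt_start=a, nt_end=b)
            start = stop + 1
        # continue to next frame; frame order tie-break is enforced by the
        # strict '>' above
    return best
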