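"""Coordinate arithmetic and HGVS annotation for a duplication-insertion SV.

A duplicated donor interval (1-based, inclusive, HGVS convention) inserted
elsewhere on the same reference sequence is described by a
:class:`BreakpointSet`.  The canonical example in this package is the 39 kb
duplication of two non-coding MSH6 exons inserted into intron 7 of MSH2,
annotated ``NC_000002.12:g.47432456_47432457ins47682947_47721794``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import DataFormatError

__all__ = ["BreakpointSet", "insertion_length", "locus_distance",
           "hgvs_ins_string", "parse_hgvs_ins", "MSH2_MSH6_DUPLICATION"]


@dataclass(frozen=True)
class BreakpointSet:
    """Breakpoints of a duplication-insertion.

    ``insertion_pos`` is the 1-based position of the first reference base
    *after* the insertion point (the conventional single-coordinate
    breakpoint, e.g. chr2:47,432,457); in HGVS the insertion is written
    between ``insertion_pos - 1`` and ``insertion_pos``.  ``donor_start`` /
    ``donor_end`` delimit the duplicated interval, 1-based inclusive.
    ``donor_orientation`` records how the donor strand is presented; it does
    not enter any arithmetic.
    """

    reference: str
    insertion_pos: int
    donor_start: int
    donor_end: int
    donor_orientation: str = "forward"

    def __post_init__(self) -> None:
        if self.insertion_pos < 2:
            raise DataFormatError("insertion_pos must leave room for a left flank")
        if self.donor_start > self.donor_end:
            raise DataFormatError("donor_start must be <= donor_end")
        if self.donor_start < 1:
            raise DataFormatError("donor coordinates are 1-based")
        if self.donor_orientation not in ("forward", "reverse"):
            raise DataFormatError(
                f"invalid donor orientation {self.donor_orientation!r}")


def insertion_length(b: BreakpointSet) -> int:
    """Length of the inserted (duplicated) sequence in bp (inclusive interval)."""
    return b.donor_end - b.donor_start + 1


def locus_distance(b: BreakpointSet) -> int:
    """Signed bp distance from the insertion point to the donor interval start.

    Positive when the donor lies downstream (higher coordinate) of the
    insertion point, negative when upstream.
    """
    return b.donor_start - b.insertion_pos


def hgvs_ins_string(b: BreakpointSet) -> str:
    """HGVS genomic insertion description, ``ref:g.<L>_<L+1>ins<S>_<E>``."""
    return (f"{b.reference}:g.{b.insertion_pos - 1}_{b.insertion_pos}"
            f"ins{b.donor_start}_{b.donor_end}")


_HGVS_INS_RE = re.compile(
    r"^(?P<ref>[^:\s]+):g\.(?P<left>\d+)_(?P<right>\d+)"
    r"ins(?P<start>\d+)_(?P<end>\d+)$")


def parse_hgvs_ins(s: str) -> BreakpointSet:
    """Parse ``ref:g.<L>_<L+1>ins<S>_<E>`` back into a BreakpointSet."""
    m = _HGVS_INS_RE.match(s.strip())
    if not m:
        raise DataFormatError(f"not a g.<L>_<R>ins<S>_<E> description: {s!r}")
    left, right = int(m["left"]), int(m["right"])
    if right != left + 1:
        raise DataFormatError(
            f"insertion flanks must be adjacent, got {left} and {right}")
    return BreakpointSet(reference=m["ref"], insertion_pos=right,
                         donor_start=int(m["start"]), donor_end=int(m["end"]))


#: The Lynch-syndrome founder duplication: two MSH6 5'UTR exons inserted
#: into MSH2 intron 7 (GRCh38 coordinates).
MSH2_MSH6_DUPLICATION = BreakpointSet(
    reference="NC_000002.12",
    insertion_pos=47_432_457,
    donor_start=47_682_947,
    donor_end=47_721_794,
)
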