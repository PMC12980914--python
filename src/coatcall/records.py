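"""Lightweight aligned-read records and CIGAR arithmetic.

The pipeline's in-memory unit is :class:`Alignment`, a plain record holding
the minimal SAM columns (QNAME FLAG RNAME POS MAPQ CIGAR SEQ).  File-level
SAM reading/writing lives in :mod:`coatcall.io`; here we keep the coordinate
arithmetic the genotyper needs: which query base sits on a reference
position, and whether a read's gap structure reproduces a panel edit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: ops that consume the reference / the query
_REF_OPS = set("MDN=X")
_QRY_OPS = set("MIS=X")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    if cigar == "*" or not cigar:
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if sum(n for _, n in ops) == 0 or "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


@dataclass
class Alignment:
    """One aligned read (minimal SAM dialect, 1-based POS)."""

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    seq: str

    def __post_init__(self) -> None:
        self._ops = parse_cigar(self.cigar)

    @property
    def ops(self) -> list[tuple[str, int]]:
        return self._ops

    @property
    def reference_end(self) -> int:
        """Last reference base covered, 1-based inclusive."""
        return self.pos + sum(n for op, n in self._ops if op in _REF_OPS) - 1

    def covers(self, start: int, end: int) -> bool:
        """True iff the aligned span includes [start, end] entirely."""
        return self.pos <= start and self.reference_end >= end

    def walk(self):
        """Yield (op, length, ref_start, qry_start) per CIGAR op (1-based ref,
        0-based query; starts refer to the first base the op consumes)."""
        ref = self.pos
        qry = 0
        for op, n in self._ops:
            yield op, n, ref, qry
            if op in _REF_OPS:
                ref += n
            if op in _QRY_OPS:
                qry += n

    def base_at(self, ref_pos: int) -> str | None:
        """Query base aligned on ``ref_pos``; None if deleted or uncovered."""
        for op, n, rs, qs in self.walk():
            if op in ("M", "=", "X") and rs <= ref_pos < rs + n:
                return self.seq[qs + (ref_pos - rs)]
            if op in ("D", "N") and rs <= ref_pos < rs + n:
                return None
        return None

    def deletion_spans(self) -> list[tuple[int, int]]:
        """Reference spans (1-based inclusive) removed by D ops."""
        return [(rs, rs + n - 1) for op, n, rs, _ in self.walk() if op == "D"]

    def insertions(self) -> list[tuple[int, str]]:
        """(ref position after which bases are inserted, inserted bases)."""
        out = []
        for op, n, rs, qs in self.walk():
            if op == "I":
                out.append((rs - 1, self.seq[qs: qs + n]))
        return out

    def matches_reference_over(self, start: int, end: int) -> bool:
        """True iff [start, end] is covered purely by M/=/X ops with no gap
        touching the span (no D overlapping it, no I strictly inside it)."""
        if not self.covers(start, end):
            return False
        for ds, de in self.deletion_spans():
            if ds <= end and de >= start:
                return False
        for after, _ in self.insertions():
            if start <= after < end:
                return False
        return True

    def to_sam_line(self) -> str:
        return "\t".join(
            [self.qname, str(self.flag), self.rname, str(self.pos),
             str(self.mapq), self.cigar, "*", "0", "0", self.seq, "*"]
        )
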