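"""Allele-depth genotyping and read-backed phasing at panel loci.

A read votes for the alternate allele only when its aligned bases and gap
structure reproduce the panel edit exactly (full deletion span, full inserted
bases, full replacement); it votes for the reference only when it matches the
reference allele across the edit footprint.  Anything else — mismatching
bases, partial gaps — is counted as "other" and excluded from the call
denominator, but reported.

Reads must span the edit footprint (one reference base beyond each edge) to
vote.  One edit in the panel — the 163 bp mocha replacement in TYR — has a
reference footprint wider than a 150 bp read, so no read can span it on the
reference allele; there, a read votes reference when it crosses either edit
boundary and matches the reference over its whole overlap with the footprint.
The alternate allele of that edit collapses to 6 bp on the carrier haplotype
and is spanned normally.

Diploid calls use simple depth thresholds (an allele needs
``min_allele_reads`` reads and ``min_allele_fraction`` of the informative
depth); the defaults reproduce every published CRFK/PG-4 call, including the
15:4 and 5:3 heterozygotes.

Phasing of nearby heterozygous pairs classifies each read spanning both
footprints as A-only / B-only / both / neither; a clean partition into the
two single-variant classes establishes a trans (compound-heterozygous)
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .panel import PanelLocus, SMALL_VARIANT_CLASSES
from .records import Alignment

__all__ = [
    "AlleleDepth",
    "GenotypeCall",
    "PhaseResult",
    "read_support",
    "count_alleles",
    "call_genotype",
    "phase_pair",
]


@dataclass(frozen=True)
class AlleleDepth:
    locus_id: str
    ref_depth: int
    alt_depth: int
    other_depth: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_depth, self.alt_depth, self.other_depth) < 0:
            raise ValueError("allele depths must be non-negative")


@dataclass(frozen=True)
class GenotypeCall:
    locus_id: str
    call: str               # hom_ref | het | hom_alt | no_call
    depths: AlleleDepth
    notation: str           # "+/+", "+/x", "x/x" with x = allele name
    reason: str = ""


@dataclass(frozen=True)
class PhaseResult:
    locus_a: str
    locus_b: str
    configuration: str      # cis | trans | unknown
    n_reads_a_only: int
    n_reads_b_only: int
    n_reads_both: int
    n_reads_neither: int
    reason: str = ""


def _footprint(locus: PanelLocus, assembly: str) -> tuple[int, int]:
    """Reference interval a voting read must engage with, footprint plus one
    anchor base each side (for INS the two bases flanking the junction)."""
    c = locus.coord(assembly)
    if locus.variant_class == "SNV":
        return c.start, c.end
    if locus.variant_class == "INS":
        return c.start, c.start + 1
    return c.start - 1, c.end + 1


def read_support(read: Alignment, locus: PanelLocus,
                 assembly: str = "fca126") -> str | None:
    """Classify one read at one small-variant locus.

    Returns 'ref', 'alt', 'other', or None when the read does not engage the
    footprint far enough to vote.
    """
    if locus.variant_class not in SMALL_VARIANT_CLASSES:
        raise ValueError(
            f"{locus.locus_id} is {locus.variant_class}: use sv_detector")
    c = locus.coord(assembly)
    f0, f1 = _footprint(locus, assembly)

    if locus.variant_class == "SNV":
        if not read.covers(c.start, c.start):
            return None
        base = read.base_at(c.start)
        if base == c.alt:
            return "alt"
        if base == c.ref:
            return "ref"
        return "other"

    # indel classes ------------------------------------------------------
    s, e = c.start, c.end
    if locus.variant_class == "DEL":
        is_alt = (s, e) in read.deletion_spans() and read.covers(f0, f1)
    elif locus.variant_class == "INS":
        is_alt = read.covers(f0, f1) and any(
            after == s and bases == c.alt for after, bases in read.insertions())
    else:  # DELINS: replacement = insertion at the left junction + deletion
        is_alt = (
            read.pos <= s - 1 and read.reference_end >= e + 1
            and (s, e) in read.deletion_spans()
            and any(after == s - 1 and bases == c.alt
                    for after, bases in read.insertions())
        )
    if is_alt:
        return "alt"

    if read.covers(f0, f1):
        return "ref" if read.matches_reference_over(f0, f1) else "other"

    # footprint wider than the read: vote from either boundary
    o0, o1 = max(read.pos, f0), min(read.reference_end, f1)
    if o0 > o1:
        return None
    crosses_left = read.covers(f0, min(f0 + 1, f1))
    crosses_right = read.covers(max(f1 - 1, f0), f1)
    if not (crosses_left or crosses_right):
        return None
    return "ref" if read.matches_reference_over(o0, o1) else "other"


def count_alleles(records: Iterable[Alignment], locus: PanelLocus,
                  assembly: str = "fca126") -> AlleleDepth:
    """Tally reference / alternate / other support at one panel locus."""
    if locus.variant_class not in SMALL_VARIANT_CLASSES:
        raise ValueError(
            f"{locus.locus_id} is {locus.variant_class}: use sv_detector")
    ref = alt = other = 0
    chrom = locus.coord(assembly).chrom
    for read in records:
        if read.rname != chrom:
            continue
        vote = read_support(read, locus, assembly)
        if vote == "ref":
            ref += 1
        elif vote == "alt":
            alt += 1
        elif vote == "other":
            other += 1
    return AlleleDepth(locus.locus_id, ref, alt, other)


def call_genotype(depth: AlleleDepth, allele_name: str = "x", *,
                  min_total: int = 5, min_allele_reads: int = 3,
                  min_allele_fraction: float = 0.15) -> GenotypeCall:
    """Diploid call from allele depths.

    "Other" reads are excluded from the denominator.  An allele is supported
    when it has at least ``min_allele_reads`` reads and at least
    ``min_allele_fraction`` of the informative (ref+alt) depth.
    """
    informative = depth.ref_depth + depth.alt_depth
    if informative < min_total:
        return GenotypeCall(depth.locus_id, "no_call", depth, "./.",
                            reason=f"informative depth {informative} < {min_total}")

    def supported(n: int) -> bool:
        return n >= min_allele_reads and n / informative >= min_allele_fraction

    ref_ok, alt_ok = supported(depth.ref_depth), supported(depth.alt_depth)
    if ref_ok and alt_ok:
        return GenotypeCall(depth.locus_id, "het", depth, f"+/{allele_name}")
    if alt_ok:
        return GenotypeCall(depth.locus_id, "hom_alt", depth,
                            f"{allele_name}/{allele_name}")
    if ref_ok:
        return GenotypeCall(depth.locus_id, "hom_ref", depth, "+/+")
    return GenotypeCall(depth.locus_id, "no_call", depth, "./.",
                        reason="no allele reaches the support thresholds")


def phase_pair(records: Iterable[Alignment], locus_a: PanelLocus,
               locus_b: PanelLocus, *, max_both: int = 0,
               min_allele_reads: int = 3,
               assembly: str = "fca126") -> PhaseResult:
    """Cis/trans configuration of two nearby heterozygous variants from read
    co-occurrence.

    Only reads spanning both footprints with an unambiguous ref/alt vote at
    each are classified.  A trans verdict (compound heterozygote) requires
    both single-variant classes at ``min_allele_reads`` or more and at most
    ``max_both`` double-variant reads; cis is the mirror image.  Pairs too
    far apart for any read to span come back 'unknown' with reason
    "no spanning reads" — an expected outcome, not an error.
    """
    a_only = b_only = both = neither = 0
    for read in records:
        va = read_support(read, locus_a, assembly)
        vb = read_support(read, locus_b, assembly)
        if va not in ("ref", "alt") or vb not in ("ref", "alt"):
            continue
        if va == "alt" and vb == "alt":
            both += 1
        elif va == "alt":
            a_only += 1
        elif vb == "alt":
            b_only += 1
        else:
            neither += 1
    total = a_only + b_only + both + neither
    if total == 0:
        return PhaseResult(locus_a.locus_id, locus_b.locus_id, "unknown",
                           0, 0, 0, 0, reason="no spanning reads")
    if a_only >= min_allele_reads and b_only >= min_allele_reads and both <= max_both:
        config, reason = "trans", ""
    elif both >= min_allele_reads and a_only <= max_both and b_only <= max_both:
        config, reason = "cis", ""
    else:
        config, reason = "unknown", "read classes do not separate cleanly"
    return PhaseResult(locus_a.locus_id, locus_b.locus_id, config,
                       a_only, b_only, both, neither, reason=reason)
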