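"""Synthetic inputs for every pipeline stage.

Real inputs for this pipeline are whole-genome alignments of a cat cell
line against a reference assembly.  This module generates statistically
matched stand-ins so every downstream stage is testable offline:

* diploid haplotype windows carrying any combination of panel alleles,
* ~150 bp paired-end reads at configurable fold-coverage and base-error
  rate, emitted as aligned records with correct placements and gap ops,
* long reads (tens of kb) spanning the KIT intron-1 junction, with or
  without a planted multi-kb endogenous-retrovirus-like insertion,
* split-read alignments across an LTR/intron junction (the blue-iris
  insertion evidence),
* per-base depth tracks with planted heterozygous/homozygous deletions
  (the salmiak / orange locus evidence), and
* gene x tissue count tables with exon lengths for the expression module.

Reference windows are fixed pseudo-random sequences keyed on the genomic
interval (not on the run seed), so they behave like bundled fixtures: the
same window is produced in every session.  Every generator is a pure
function of its arguments and seed, and each returns a truth record rich
enough to recompute the expected downstream answer by brute force.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .panel import Coord, PanelError, PanelLocus
from .records import Alignment

__all__ = [
    "SynthConfig",
    "GenotypeSpec",
    "Haplotype",
    "HaplotypePair",
    "KitRegion",
    "reference_window",
    "make_haplotypes",
    "simulate_short_reads",
    "simulate_long_reads",
    "simulate_junction_alignments",
    "simulate_depth_track",
    "simulate_counts",
    "kit_region",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Simulation parameters mirroring the study's sequencing conditions:
    150 bp paired-end short reads at ~23x genome-wide coverage, long reads
    averaging tens of kb, and a planted insertion exceeding 7 kb."""

    read_length: int = 150
    mean_depth: float = 23.0
    base_error_rate: float = 0.001
    long_read_mean_length: int = 25_000
    insertion_sequence_length: int = 7_400
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be in [0, 1]")
        for name in ("read_length", "long_read_mean_length", "insertion_sequence_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.rng_seed, salt))


@dataclass(frozen=True)
class GenotypeSpec:
    """Per-locus assignment of the two haplotypes to ref/alt alleles.

    ``haplotypes`` maps locus_id -> ("ref"|"alt", "ref"|"alt").  Loci not
    mentioned are ref/ref.  For X-linked loci with sex="XY" only the first
    haplotype is read (single X copy).
    """

    haplotypes: dict[str, tuple[str, str]] = field(default_factory=dict)
    sex: str = "unknown"

    def __post_init__(self) -> None:
        for locus_id, pair in self.haplotypes.items():
            if tuple(pair) != pair or len(pair) != 2 or not set(pair) <= {"ref", "alt"}:
                raise ValueError(f"bad haplotype assignment for {locus_id}: {pair!r}")
        if self.sex not in ("XX", "XY", "unknown"):
            raise ValueError(f"bad sex {self.sex!r}")

    def alleles(self, locus_id: str) -> tuple[str, str]:
        return self.haplotypes.get(locus_id, ("ref", "ref"))


def _fixed_seq(tag: str, length: int) -> str:
    """Deterministic pseudo-random sequence keyed only on ``tag`` — a bundled
    fixture in code form."""
    rng = np.random.default_rng(zlib.crc32(tag.encode()))
    return "".join(rng.choice(_BASES, size=length))


def reference_window(chrom: str, start: int, end: int,
                     snv_refs: dict[int, str] | None = None) -> str:
    """Fixed random reference sequence for [start, end]; positions listed in
    ``snv_refs`` (genomic pos -> base) are forced so panel SNV ref alleles
    are honoured."""
    seq = list(_fixed_seq(f"refwin:{chrom}:{start}-{end}", end - start + 1))
    for pos, base in (snv_refs or {}).items():
        if start <= pos <= end:
            seq[pos - start] = base
    return "".join(seq)


def locus_edit(locus: PanelLocus, assembly: str = "fca126") -> tuple[str, int, int, str]:
    """(kind, start, end, alt) of the alt edit in genomic coordinates.

    INS edits are anchored after ``start`` (the left flanking base)."""
    c: Coord = locus.coord(assembly)
    if locus.variant_class == "SNV":
        return ("SNV", c.start, c.end, c.alt)
    if locus.variant_class == "DEL":
        return ("DEL", c.start, c.end, "")
    if locus.variant_class == "INS":
        return ("INS", c.start, c.start, c.alt)
    if locus.variant_class == "DELINS":
        return ("DELINS", c.start, c.end, c.alt)
    raise PanelError(f"{locus.locus_id}: structural class {locus.variant_class} "
                     "has no small-variant edit; use the SV generators")


@dataclass
class Haplotype:
    """A window haplotype with its alignment structure against the reference.

    ``blocks`` is an ordered list of (op, ref_start, hap_start, length) with
    op in M/I/D; ref_start is 1-based genomic, hap_start 0-based into ``seq``
    (for D blocks hap_start is the insertion point, length the deleted span).
    """

    chrom: str
    window_start: int
    seq: str
    blocks: list[tuple[str, int, int, int]]
    edits: list[tuple[str, int, int, str]]

    def __len__(self) -> int:
        return len(self.seq)

    def index_of(self, genomic_pos: int) -> int:
        """Haplotype offset of the base aligned on ``genomic_pos`` (for
        positions inside a deletion, the offset of the deletion point)."""
        for op, ref_start, hap_start, length in self.blocks:
            if op == "I":
                continue
            if ref_start <= genomic_pos < ref_start + length:
                if op == "D":
                    return hap_start
                return hap_start + (genomic_pos - ref_start)
        raise ValueError(f"position {genomic_pos} outside haplotype window")


@dataclass
class HaplotypePair:
    chrom: str
    window_start: int
    window_end: int
    reference: str
    hap1: Haplotype
    hap2: Haplotype
    truth: dict


def _build_haplotype(chrom: str, wstart: int, ref: str,
                     edits: Sequence[tuple[str, int, int, str]]) -> Haplotype:
    edits = sorted(edits, key=lambda e: e[1])
    wend = wstart + len(ref) - 1
    for (k1, s1, e1, _), (k2, s2, e2, _) in zip(edits, edits[1:]):
        if s2 <= e1:
            raise ValueError("overlapping edits in one haplotype")
    seq: list[str] = []
    blocks: list[tuple[str, int, int, int]] = []
    ref_cursor = wstart

    def emit_match(upto: int) -> None:
        nonlocal ref_cursor
        if upto >= ref_cursor:
            chunk = ref[ref_cursor - wstart: upto - wstart + 1]
            blocks.append(("M", ref_cursor, len("".join(seq)), len(chunk)))
            seq.append(chunk)
            ref_cursor = upto + 1

    for kind, s, e, alt in edits:
        if not (wstart <= s and e <= wend):
            raise ValueError(f"edit {kind}@{s} outside window {wstart}-{wend}")
        if kind == "SNV":
            emit_match(s - 1)
            blocks.append(("M", s, len("".join(seq)), 1))
            seq.append(alt)
            ref_cursor = s + 1
        elif kind == "DEL":
            emit_match(s - 1)
            blocks.append(("D", s, len("".join(seq)), e - s + 1))
            ref_cursor = e + 1
        elif kind == "INS":
            emit_match(s)  # left anchor base stays reference
            blocks.append(("I", s + 1, len("".join(seq)), len(alt)))
            seq.append(alt)
        elif kind == "DELINS":
            emit_match(s - 1)
            blocks.append(("I", s, len("".join(seq)), len(alt)))
            seq.append(alt)
            blocks.append(("D", s, len("".join(seq)), e - s + 1))
            ref_cursor = e + 1
        else:
            raise ValueError(f"unknown edit kind {kind}")
    emit_match(wend)
    hap_seq = "".join(seq)
    # merge adjacent M blocks for cleanliness
    merged: list[tuple[str, int, int, int]] = []
    for b in blocks:
        if merged and merged[-1][0] == "M" and b[0] == "M" \
                and merged[-1][1] + merged[-1][3] == b[1] \
                and merged[-1][2] + merged[-1][3] == b[2]:
            prev = merged.pop()
            b = ("M", prev[1], prev[2], prev[3] + b[3])
        merged.append(b)
    return Haplotype(chrom, wstart, hap_seq, merged, list(edits))


def make_haplotypes(spec: GenotypeSpec, loci: Sequence[PanelLocus],
                    pad: int = 400, assembly: str = "fca126") -> HaplotypePair:
    """Build the two haplotype sequences of one locus window.

    All ``loci`` must share a chromosome; the window spans their combined
    footprint plus ``pad`` on each side.  Each haplotype receives exactly the
    alt edits its spec assignment requests; the truth record stores the edit
    positions for oracle checks.
    """
    if not loci:
        raise ValueError("no loci given")
    from .panel import panel_by_id
    known = set(panel_by_id()) | {lo.locus_id for lo in loci}
    unknown = set(spec.haplotypes) - known
    if unknown:
        raise PanelError(f"spec references loci absent from panel: {sorted(unknown)}")
    coords = [lo.coord(assembly) for lo in loci]
    chroms = {c.chrom for c in coords}
    if len(chroms) != 1:
        raise ValueError(f"loci span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    wstart = max(1, min(c.start for c in coords) - pad)
    wend = max(c.end for c in coords) + pad
    snv_refs = {c.start: c.ref for lo, c in zip(loci, coords) if lo.variant_class == "SNV"}
    ref = reference_window(chrom, wstart, wend, snv_refs)

    per_hap_edits: tuple[list, list] = ([], [])
    truth_loci = {}
    for lo in loci:
        a1, a2 = spec.alleles(lo.locus_id)
        edit = locus_edit(lo, assembly)
        for hap_idx, allele in enumerate((a1, a2)):
            if allele == "alt":
                per_hap_edits[hap_idx].append(edit)
        truth_loci[lo.locus_id] = {
            "edit": edit, "hap1": a1, "hap2": a2,
            "variant_class": lo.variant_class,
        }
    hap1 = _build_haplotype(chrom, wstart, ref, per_hap_edits[0])
    hap2 = _build_haplotype(chrom, wstart, ref, per_hap_edits[1])
    truth = {"chrom": chrom, "window": [wstart, wend], "loci": truth_loci,
             "sex": spec.sex}
    return HaplotypePair(chrom, wstart, wend, ref, hap1, hap2, truth)


# ---------------------------------------------------------------------------
# short reads

def _read_alignment(hap: Haplotype, q0: int, q1: int) -> tuple[int, str]:
    """POS and CIGAR of the haplotype slice [q0, q1) against the reference."""
    ops: list[tuple[str, int]] = []
    pos: int | None = None
    for op, ref_start, hap_start, length in hap.blocks:
        if op == "D":
            # deletions sit between haplotype bases at hap_start
            if q0 < hap_start < q1:
                ops.append(("D", length))
            continue
        h_end = hap_start + length
        lo, hi = max(q0, hap_start), min(q1, h_end)
        if lo >= hi:
            continue
        if op == "M":
            if pos is None:
                pos = ref_start + (lo - hap_start)
            ops.append(("M", hi - lo))
        else:  # I
            ops.append(("I", hi - lo))
    # unanchored inserted bases at the edges become soft clips
    while ops and ops[0][0] in ("D",):
        ops.pop(0)
    while ops and ops[-1][0] in ("D",):
        ops.pop()
    if ops and ops[0][0] == "I":
        ops[0] = ("S", ops[0][1])
    if ops and ops[-1][0] == "I":
        ops[-1] = ("S", ops[-1][1])
    if pos is None:
        raise ValueError("read has no reference-anchored bases")
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return pos, "".join(f"{n}{op}" for op, n in merged)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def _required_interval(hap: Haplotype, locus: PanelLocus, read_length: int,
                       assembly: str) -> tuple[int, int]:
    """Haplotype-coordinate interval a read must contain to cast an
    unambiguous ref/alt vote at ``locus`` on this haplotype."""
    kind, s, e, alt = locus_edit(locus, assembly)
    carries_alt = (kind, s, e, alt) in hap.edits
    if carries_alt:
        if kind == "SNV":
            return hap.index_of(s), hap.index_of(s)
        if kind == "INS":
            return hap.index_of(s), hap.index_of(s + 1)
        return hap.index_of(s - 1), hap.index_of(e + 1)
    # reference allele: span the footprint, or a boundary if it is too wide
    if kind == "SNV":
        f0 = f1 = s
    elif kind == "INS":
        f0, f1 = s, s + 1
    else:
        f0, f1 = s - 1, e + 1
    if f1 - f0 + 1 <= read_length:
        return hap.index_of(f0), hap.index_of(f1)
    return hap.index_of(f0), hap.index_of(f0) + 1


def simulate_short_reads(pair: HaplotypePair, config: SynthConfig,
                         fragment_mean: int = 380, fragment_sd: int = 25,
                         reads_per_hap: tuple[int, int] | None = None,
                         focus_loci: Sequence[PanelLocus] | None = None,
                         assembly: str = "fca126",
                         ) -> list[Alignment]:
    """Paired 150 bp reads sampled uniformly from the two haplotypes.

    Coverage targets ``config.mean_depth`` over the window unless
    ``reads_per_hap`` pins exact single-read counts per haplotype (used when
    a printed read composition must be reproduced); pinned reads are placed
    so each one spans the voting footprint of every ``focus_loci`` locus.
    Deterministic under the config seed.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = config.rng(salt=1)
    rl = config.read_length
    out: list[Alignment] = []
    haps = (pair.hap1, pair.hap2)

    def emit(hap: Haplotype, q0: int, name: str, flag: int) -> None:
        q1 = min(q0 + rl, len(hap))
        pos, cigar = _read_alignment(hap, q0, q1)
        seq = _apply_errors(hap.seq[q0:q1], config.base_error_rate, rng)
        out.append(Alignment(name, flag, hap.chrom, pos, 60, cigar, seq))

    if reads_per_hap is not None:
        for h_idx, n in enumerate(reads_per_hap):
            hap = haps[h_idx]
            if len(hap) < rl:
                raise ValueError("haplotype shorter than read length")
            if focus_loci:
                i0 = min(_required_interval(hap, lo, rl, assembly)[0]
                         for lo in focus_loci)
                i1 = max(_required_interval(hap, lo, rl, assembly)[1]
                         for lo in focus_loci)
                if i1 - i0 + 1 > rl:
                    raise ValueError("focus loci span exceeds read length")
            else:
                mid = len(hap) // 2
                i0 = i1 = mid
            lo_q = max(0, i1 - rl + 1)
            hi_q = min(i0, len(hap) - rl)
            if lo_q > hi_q:
                raise ValueError("window too small to place pinned reads")
            for i in range(n):
                q0 = int(rng.integers(lo_q, hi_q + 1))
                emit(hap, q0, f"pin_h{h_idx + 1}_{i:04d}", 0)
        return out

    window_len = pair.window_end - pair.window_start + 1
    n_pairs = max(1, round(config.mean_depth * window_len / (2 * rl)))
    for i in range(n_pairs):
        hap = haps[int(rng.integers(2))]
        frag = int(np.clip(rng.normal(fragment_mean, fragment_sd), 2 * rl, None))
        frag = min(frag, len(hap))
        start = int(rng.integers(0, max(1, len(hap) - frag + 1)))
        name = f"sim{i:06d}"
        emit(hap, start, name, 99)
        emit(hap, start + frag - rl, name, 147)
    return out


# ---------------------------------------------------------------------------
# long reads (KIT intron 1 / FERV1-homolog insertion)

@dataclass(frozen=True)
class KitRegion:
    """Fixture geometry for the KIT intron-1 insertion site: two reference
    flanks meeting at the junction, plus the pseudo-FERV1 insert probe."""

    flank_left: str
    flank_right: str
    insert: str

    @property
    def junction(self) -> int:
        return len(self.flank_left)


def kit_region(config: SynthConfig, flank_length: int = 6_000) -> KitRegion:
    """Deterministic stand-in for the KIT intron-1 region and the FERV1
    homolog.  The insert is a fixed random sequence of the configured length;
    detection logic must not rely on its content."""
    return KitRegion(
        flank_left=_fixed_seq("kit_intron1_flank_left", flank_length),
        flank_right=_fixed_seq("kit_intron1_flank_right", flank_length),
        insert=_fixed_seq("pseudo_ferv1_insert", config.insertion_sequence_length),
    )


def simulate_long_reads(n_with_insertion: int, n_without: int,
                        config: SynthConfig,
                        region: KitRegion | None = None,
                        ) -> tuple[list[tuple[str, str]], list[dict], KitRegion]:
    """Long reads spanning the KIT intron-1 junction.

    "with" reads carry the full planted insert between the two flanks;
    "without" reads cross the junction uninterrupted.  Returns
    (named read sequences, per-read truth records, region fixture).
    """
    if n_with_insertion < 0 or n_without < 0:
        raise ValueError("read counts must be non-negative")
    if n_with_insertion + n_without == 0:
        raise ValueError("at least one read required")
    region = region or kit_region(config)
    rng = config.rng(salt=2)
    reads: list[tuple[str, str]] = []
    truth: list[dict] = []
    min_flank = 1_000

    def flank_spans() -> tuple[int, int]:
        left = int(rng.integers(min_flank, len(region.flank_left) + 1))
        right = int(rng.integers(min_flank, len(region.flank_right) + 1))
        return left, right

    for i in range(n_with_insertion):
        left, right = flank_spans()
        seq = region.flank_left[-left:] + region.insert + region.flank_right[:right]
        seq = _apply_errors(seq, config.base_error_rate, rng)
        name = f"lr_ins_{i:03d}"
        reads.append((name, seq))
        truth.append({"name": name, "has_insertion": True,
                      "insertion_length": len(region.insert),
                      "left_flank": left, "right_flank": right})
    for i in range(n_without):
        left, right = flank_spans()
        seq = region.flank_left[-left:] + region.flank_right[:right]
        seq = _apply_errors(seq, config.base_error_rate, rng)
        name = f"lr_ref_{i:03d}"
        reads.append((name, seq))
        truth.append({"name": name, "has_insertion": False,
                      "insertion_length": 0,
                      "left_flank": left, "right_flank": right})
    return reads, truth, region


# ---------------------------------------------------------------------------
# split-read junction evidence (PAX3 intron 4 LTR insertions)

def simulate_junction_alignments(
        n_junction: int, n_background: int, config: SynthConfig,
        target_chrom: str = "C1", target_start: int = 205_831_000,
        target_length: int = 4_000, insert_name: str = "FERV1-LTR",
        insert_length: int = 400,
) -> tuple[list[Alignment], list[Alignment], dict]:
    """Short-read alignments of one read set against a target intron window
    and against an LTR sequence.

    Junction reads originate from an allele with the LTR inserted at the
    window midpoint: each appears once in the target alignments (flank part
    aligned, insert part soft-clipped) and once in the insert alignments
    (reverse arrangement), under the same read name.  Background reads map
    only to the target.  Truth lists the junction read names.
    """
    if n_junction < 0 or n_background < 0:
        raise ValueError("read counts must be non-negative")
    rng = config.rng(salt=3)
    rl = config.read_length
    target = reference_window(target_chrom, target_start,
                              target_start + target_length - 1)
    insert = _fixed_seq(f"ltr:{insert_name}", insert_length)
    mid = target_length // 2  # 0-based offset of last base before insertion
    vs_target: list[Alignment] = []
    vs_insert: list[Alignment] = []
    junction_names = []
    for i in range(n_junction):
        name = f"jx_{i:04d}"
        junction_names.append(name)
        k = int(rng.integers(40, rl - 40 + 1))  # bases on the target side
        left_side = bool(rng.integers(2))
        if left_side:
            tpart = target[mid - k + 1: mid + 1]
            ipart = insert[: rl - k]
            seq = _apply_errors(tpart + ipart, config.base_error_rate, rng)
            vs_target.append(Alignment(name, 0, target_chrom,
                                       target_start + mid - k + 1, 60,
                                       f"{k}M{rl - k}S", seq))
            vs_insert.append(Alignment(name, 0, insert_name, 1, 60,
                                       f"{k}S{rl - k}M", seq))
        else:
            ipart = insert[-(rl - k):]
            tpart = target[mid + 1: mid + 1 + k]
            seq = _apply_errors(ipart + tpart, config.base_error_rate, rng)
            vs_target.append(Alignment(name, 0, target_chrom,
                                       target_start + mid + 1, 60,
                                       f"{rl - k}S{k}M", seq))
            vs_insert.append(Alignment(name, 0, insert_name,
                                       insert_length - (rl - k) + 1, 60,
                                       f"{rl - k}M{k}S", seq))
    for i in range(n_background):
        name = f"bg_{i:04d}"
        q0 = int(rng.integers(0, target_length - rl + 1))
        seq = _apply_errors(target[q0: q0 + rl], config.base_error_rate, rng)
        vs_target.append(Alignment(name, 0, target_chrom,
                                   target_start + q0, 60, f"{rl}M", seq))
    truth = {"junction_reads": junction_names, "insert_name": insert_name,
             "target_window": [target_start, target_start + target_length - 1]}
    return vs_target, vs_insert, truth


# ---------------------------------------------------------------------------
# depth tracks (salmiak / orange deletion evidence)

def simulate_depth_track(region_length: int, flank_length: int,
                         baseline_depth: float,
                         deletion_genotype: str = "none",
                         noise: float = 0.0, seed: int = 0,
                         chrom: str = "B1", start: int = 1):
    """Per-base depth over [flank | region | flank] with a planted deletion.

    Depths are negative-binomially dispersed around the baseline
    (variance = m + noise * m^2); ``noise`` = 0 gives exact expected values.
    The candidate region is scaled x1 / x0.5 / x0 for genotype
    none / het / hom.
    """
    from .sv_detector import DepthTrack  # local import avoids cycle at import time

    if region_length <= 0 or flank_length <= 0:
        raise ValueError("region and flank lengths must be positive")
    if deletion_genotype not in ("none", "het", "hom"):
        raise ValueError(f"bad deletion_genotype {deletion_genotype!r}")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    scale = {"none": 1.0, "het": 0.5, "hom": 0.0}[deletion_genotype]
    rng = np.random.default_rng((int(seed), 4))
    means = np.concatenate([
        np.full(flank_length, baseline_depth),
        np.full(region_length, baseline_depth * scale),
        np.full(flank_length, baseline_depth),
    ])
    if noise == 0:
        values = means.astype(float)
    else:
        size = 1.0 / noise
        values = np.zeros_like(means)
        pos = means > 0
        p = size / (size + means[pos])
        values[pos] = rng.negative_binomial(size, p).astype(float)
    region_start = start + flank_length
    region_end = region_start + region_length - 1
    return DepthTrack(chrom=chrom, start=start, depths=values), (region_start, region_end)


# ---------------------------------------------------------------------------
# expression counts

def simulate_counts(n_genes: int, n_tissues: int,
                    exon_lengths: Sequence[int] | None = None,
                    seed: int = 0, mean_count: float = 500.0,
                    dispersion: float = 0.4):
    """Gene x tissue non-negative integer counts plus exon lengths.

    Gene baselines are log-normal; counts are negative binomial around the
    per-gene baseline.  Deterministic under ``seed``.
    """
    import pandas as pd

    if n_genes <= 0 or n_tissues <= 0:
        raise ValueError("n_genes and n_tissues must be positive")
    rng = np.random.default_rng((int(seed), 5))
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    tissues = [f"tissue{j:02d}" for j in range(n_tissues)]
    if exon_lengths is None:
        exon_lengths = rng.integers(500, 10_001, size=n_genes)
    lengths = pd.Series(np.asarray(exon_lengths, dtype=int), index=genes,
                        name="exon_length")
    base = mean_count * rng.lognormal(0.0, 1.0, size=n_genes)
    size = 1.0 / dispersion
    means = np.outer(base, rng.lognormal(0.0, 0.25, size=n_tissues))
    p = size / (size + means)
    counts = rng.negative_binomial(size, p)
    return pd.DataFrame(counts, index=genes, columns=tissues), lengths
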