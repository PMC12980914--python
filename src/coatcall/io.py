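"""Readers and writers for the external formats the pipeline touches.

SAM handling targets the minimal dialect the pipeline emits (the 11
mandatory columns; header optional; CIGAR ops M/I/D/S/=/X).  Files with a
header are parsed through pysam; headerless files fall back to a strict
column parser.  All readers reject malformed input with a located error
(file and line) instead of skipping silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .genotyper import AlleleDepth, GenotypeCall, PhaseResult
from .records import Alignment
from .sv_detector import DepthTrack, SVCall

__all__ = [
    "read_sam", "write_sam", "read_fasta", "write_fasta",
    "read_depth_track", "write_depth_track",
    "write_calls", "read_calls", "write_json_report", "meta_block",
]

_SQ_LEN = 500_000_000  # generous upper bound for cat chromosome lengths


class FormatError(ValueError):
    """Malformed input file; message carries file and line."""


def meta_block(seed: int | None = None, config: dict | None = None) -> dict:
    """Provenance stamp embedded in every output."""
    cfg = json.dumps(config or {}, sort_keys=True)
    return {
        "tool": "coatcall",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg.encode()).hexdigest()[:12],
    }


# -- SAM --------------------------------------------------------------------

def write_sam(records: Iterable[Alignment], path: str | Path) -> None:
    records = list(records)
    rnames = sorted({r.rname for r in records})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("@HD\tVN:1.6\n")
        for rn in rnames:
            fh.write(f"@SQ\tSN:{rn}\tLN:{_SQ_LEN}\n")
        for r in records:
            fh.write(r.to_sam_line() + "\n")


def _read_sam_pysam(path: Path) -> list[Alignment]:
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            out.append(Alignment(
                seg.query_name, seg.flag, seg.reference_name or "*",
                (seg.reference_start or 0) + 1, seg.mapping_quality,
                seg.cigarstring or "*", seg.query_sequence or ""))
    return out


def read_sam(path: str | Path) -> list[Alignment]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("@"):
        try:
            return _read_sam_pysam(path)
        except NotImplementedError:
            pass  # header without @SQ lines (e.g. zero records): parse manually
    out: list[Alignment] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(f"{path}: line {lineno}: "
                                  f"{len(fields)} columns, expected >= 11")
            try:
                out.append(Alignment(fields[0], int(fields[1]), fields[2],
                                     int(fields[3]), int(fields[4]),
                                     fields[5], fields[9]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


# -- FASTA ------------------------------------------------------------------

def write_fasta(seqs: Sequence[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    out = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


# -- depth tracks -----------------------------------------------------------

def write_depth_track(track: DepthTrack, path: str | Path,
                      meta: dict | None = None) -> None:
    import numpy as np

    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("#chrom\tpos\tdepth\n")
        for i, d in enumerate(np.asarray(track.depths)):
            fh.write(f"{track.chrom}\t{track.start + i}\t{d:g}\n")


def read_depth_track(path: str | Path) -> DepthTrack:
    import numpy as np

    chrom, start, depths = None, None, []
    expected = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            try:
                pos, depth = int(fields[1]), float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if chrom is None:
                chrom, start, expected = fields[0], pos, pos
            elif fields[0] != chrom or pos != expected:
                raise FormatError(f"{path}: line {lineno}: positions must be "
                                  "contiguous on one chromosome")
            depths.append(depth)
            expected += 1
    if chrom is None:
        raise FormatError(f"{path}: empty depth track")
    return DepthTrack(chrom=chrom, start=start, depths=np.array(depths))


# -- genotype / SV call tables ---------------------------------------------

_CALL_HEADER = ("CHROM", "POS", "ID", "REF", "ALT", "GT", "DP", "AD",
                "CALL", "NOTATION", "EVIDENCE", "DETAIL")


def write_calls(path: str | Path, calls: Sequence[GenotypeCall],
                sv_calls: Sequence[SVCall] = (),
                phases: Sequence[PhaseResult] = (),
                panel_by_id: dict | None = None,
                meta: dict | None = None) -> None:
    """VCF-like TSV of genotype and SV calls plus phase lines."""
    from .panel import panel_by_id as _panel_index

    idx = panel_by_id or _panel_index()
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("#" + "\t".join(_CALL_HEADER) + "\n")
        for call in calls:
            lo = idx[call.locus_id]
            c = lo.coord_fca126 or lo.coord_anams
            d = call.depths
            fh.write("\t".join([
                c.chrom, str(c.start), call.locus_id,
                c.ref or ".", c.alt or "-",
                {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
                 "no_call": "./."}[call.call],
                str(d.ref_depth + d.alt_depth + d.other_depth),
                f"{d.ref_depth},{d.alt_depth}",
                call.call, call.notation, "pileup", call.reason or ".",
            ]) + "\n")
        for sv in sv_calls:
            lo = idx.get(sv.locus_id)
            c = (lo.coord_fca126 or lo.coord_anams) if lo else None
            fh.write("\t".join([
                c.chrom if c else ".", str(c.start) if c else ".",
                sv.locus_id, ".", "<SV>", ".", ".", ".",
                sv.genotype, ".", sv.evidence_type,
                json.dumps(sv.stats, sort_keys=True),
            ]) + "\n")
        for ph in phases:
            fh.write("\t".join([
                ".", ".", f"{ph.locus_a}|{ph.locus_b}", ".", ".", ".", ".", ".",
                ph.configuration, ".", "phase",
                json.dumps({"a_only": ph.n_reads_a_only,
                            "b_only": ph.n_reads_b_only,
                            "both": ph.n_reads_both,
                            "neither": ph.n_reads_neither,
                            "reason": ph.reason}, sort_keys=True),
            ]) + "\n")


def read_calls(path: str | Path
               ) -> tuple[list[GenotypeCall], list[SVCall], list[PhaseResult]]:
    calls: list[GenotypeCall] = []
    svs: list[SVCall] = []
    phases: list[PhaseResult] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_CALL_HEADER):
                raise FormatError(f"{path}: line {lineno}: expected "
                                  f"{len(_CALL_HEADER)} columns")
            (_, _, lid, _, _, _, _, ad, call, notation, evidence,
             detail) = fields
            if evidence == "pileup":
                ref_d, alt_d = (int(x) for x in ad.split(","))
                calls.append(GenotypeCall(
                    lid, call, AlleleDepth(lid, ref_d, alt_d), notation,
                    reason="" if detail == "." else detail))
            elif evidence == "phase":
                stats = json.loads(detail)
                a, b = lid.split("|")
                phases.append(PhaseResult(
                    a, b, call, stats["a_only"], stats["b_only"],
                    stats["both"], stats["neither"], stats.get("reason", "")))
            else:
                svs.append(SVCall(lid, evidence, call,
                                  stats=json.loads(detail)))
    return calls, svs, phases


def write_json_report(obj, path: str | Path, seed: int | None = None,
                      config: dict | None = None) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = {"meta": meta_block(seed, config), "report": obj}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
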