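"""The coat/iris variant panel: thirteen pigmentation and coat-morphology genes.

The panel is shipped as a versioned TSV (``data/panel.tsv``), one row per
allele, with 1-based inclusive coordinates in both current cat reference
assemblies (F.catus_Fca126_mat1.0 and AnAms1.0).  It is the single source of
truth for every other module: the genotyper and structural-variant detector
look up footprints here, the synthetic-read generator plants edits here, and
the phenotype engine consumes the inheritance and epistasis annotations.

Notes on the encoding
---------------------
* SNV rows carry explicit genomic-strand ref/alt bases.
* DEL/DELINS rows use ``.`` for ref, meaning "the reference span given by the
  coordinates"; the deleted bases themselves are taken from whatever
  reference window is in use (real assembly or synthetic stand-in).
* INS rows give the two bases flanking the insertion point as start/end.
* The orange locus (ARHGAP36) has no Fca126 coordinates: the maternal Fca126
  haplotype itself carries the deletion, so that locus is only addressable on
  AnAms1.0.
* Inheritance annotations carry a provenance column: ``study`` where the
  curating study states the mode, ``external`` where it comes from the
  primary literature on the allele.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "PanelLocus",
    "load_panel",
    "load_study_genotypes",
    "locus_window",
    "panel_by_id",
    "write_panel",
    "PanelError",
    "SMALL_VARIANT_CLASSES",
    "SV_CLASSES",
    "CAT_CHROMOSOMES",
]

SMALL_VARIANT_CLASSES = frozenset({"SNV", "DEL", "INS", "DELINS"})
SV_CLASSES = frozenset({"SV_DEL", "SV_INS"})
VARIANT_CLASSES = SMALL_VARIANT_CLASSES | SV_CLASSES

INHERITANCE_MODES = frozenset(
    {"recessive", "dominant", "dominant_spotting", "x_linked", "unknown"}
)

#: Chromosome naming of the domestic-cat karyotype (18 autosome pairs + X).
CAT_CHROMOSOMES = frozenset(
    [f"A{i}" for i in range(1, 4)]
    + [f"B{i}" for i in range(1, 5)]
    + [f"C{i}" for i in range(1, 3)]
    + [f"D{i}" for i in range(1, 5)]
    + [f"E{i}" for i in range(1, 4)]
    + [f"F{i}" for i in range(1, 3)]
    + ["X"]
)

_PANEL_COLUMNS = [
    "locus_id", "gene", "trait", "allele_name", "variant_class",
    "cds_notation",
    "chrom_fca126", "start_fca126", "end_fca126", "ref_fca126", "alt_fca126",
    "chrom_anams", "start_anams", "end_anams", "ref_anams", "alt_anams",
    "inheritance", "inheritance_source", "epistasis_tags",
]


class PanelError(ValueError):
    """Malformed panel file or inconsistent locus definition."""


@dataclass(frozen=True)
class Coord:
    """A 1-based inclusive genomic interval with ref/alt allele strings."""

    chrom: str
    start: int
    end: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PanelError(f"start {self.start} > end {self.end} on {self.chrom}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PanelLocus:
    """One panel row: a single allele of one gene with dual-assembly coordinates."""

    locus_id: str
    gene: str
    trait: str
    allele_name: str
    variant_class: str
    cds_notation: str
    coord_fca126: Coord | None   # None where the assembly lacks the locus
    coord_anams: Coord | None
    inheritance: str
    inheritance_source: str = "external"
    epistasis_tags: tuple[str, ...] = field(default_factory=tuple)

    def coord(self, assembly: str) -> Coord:
        c = {"fca126": self.coord_fca126, "anams": self.coord_anams}.get(assembly)
        if assembly not in ("fca126", "anams"):
            raise PanelError(f"unknown assembly {assembly!r}")
        if c is None:
            raise PanelError(
                f"coordinate absent in assembly {assembly!r} for locus {self.locus_id}"
            )
        return c

    @property
    def is_sv(self) -> bool:
        return self.variant_class in SV_CLASSES


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("coatcall").joinpath("data", name))


def _parse_coord(row: dict, suffix: str, locus_id: str, lineno: int) -> Coord | None:
    chrom = row[f"chrom_{suffix}"]
    if chrom in ("absent", "", "."):
        return None
    if chrom not in CAT_CHROMOSOMES:
        raise PanelError(f"line {lineno} ({locus_id}): unknown chromosome {chrom!r}")
    try:
        start = int(row[f"start_{suffix}"])
        end = int(row[f"end_{suffix}"])
    except ValueError as exc:
        raise PanelError(f"line {lineno} ({locus_id}): non-integer coordinate") from exc
    return Coord(chrom, start, end, row[f"ref_{suffix}"], row[f"alt_{suffix}"])


def _validate(locus: PanelLocus, lineno: int) -> None:
    if locus.variant_class not in VARIANT_CLASSES:
        raise PanelError(
            f"line {lineno} ({locus.locus_id}): bad variant_class {locus.variant_class!r}"
        )
    if locus.inheritance not in INHERITANCE_MODES:
        raise PanelError(
            f"line {lineno} ({locus.locus_id}): bad inheritance {locus.inheritance!r}"
        )
    for coord in (locus.coord_fca126, locus.coord_anams):
        if coord is None:
            continue
        if locus.variant_class == "SNV":
            if len(coord.ref) != 1 or len(coord.alt) != 1 or coord.span != 1:
                raise PanelError(
                    f"line {lineno} ({locus.locus_id}): SNV must be a single base"
                )
        elif locus.variant_class == "INS":
            if coord.span != 2 or not coord.alt:
                raise PanelError(
                    f"line {lineno} ({locus.locus_id}): INS needs 2-base anchor and alt bases"
                )


def load_panel(path: str | Path | None = None) -> list[PanelLocus]:
    """Load the variant panel (the bundled TSV by default).

    Returns all rows in file order.  Raises :class:`PanelError` naming the
    offending line on any malformed row, duplicated locus_id, or coordinate
    inconsistency.
    """
    path = _data_path("panel.tsv") if path is None else Path(path)
    loci: list[PanelLocus] = []
    seen: set[str] = set()
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split("\t")
                if fields and fields[0] == "locus_id":
                    header = fields
                continue
            if header is None:
                header = _PANEL_COLUMNS
            values = line.split("\t")
            if len(values) < len(header) - 1:
                raise PanelError(f"{path}: line {lineno}: expected {len(header)} columns")
            values += [""] * (len(header) - len(values))
            row = dict(zip(header, values))
            locus_id = row["locus_id"]
            if locus_id in seen:
                raise PanelError(f"{path}: line {lineno}: duplicate locus_id {locus_id!r}")
            seen.add(locus_id)
            tags = tuple(t for t in row["epistasis_tags"].split(",") if t)
            locus = PanelLocus(
                locus_id=locus_id,
                gene=row["gene"],
                trait=row["trait"],
                allele_name=row["allele_name"],
                variant_class=row["variant_class"],
                cds_notation=row["cds_notation"],
                coord_fca126=_parse_coord(row, "fca126", locus_id, lineno),
                coord_anams=_parse_coord(row, "anams", locus_id, lineno),
                inheritance=row["inheritance"],
                inheritance_source=row["inheritance_source"],
                epistasis_tags=tags,
            )
            _validate(locus, lineno)
            loci.append(locus)
    if not loci:
        raise PanelError(f"{path}: empty panel")
    return loci


def panel_by_id(loci: Iterable[PanelLocus] | None = None) -> dict[str, PanelLocus]:
    """Index panel loci by locus_id (loads the bundled panel if none given)."""
    if loci is None:
        loci = load_panel()
    return {locus.locus_id: locus for locus in loci}


def write_panel(loci: Iterable[PanelLocus], path: str | Path) -> None:
    """Write loci to the on-disk TSV format (round-trips with load_panel)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_PANEL_COLUMNS) + "\n")
        for lo in loci:
            def cfields(c: Coord | None) -> list[str]:
                if c is None:
                    return ["absent", "0", "0", "", ""]
                return [c.chrom, str(c.start), str(c.end), c.ref, c.alt]

            fh.write(
                "\t".join(
                    [
                        lo.locus_id, lo.gene, lo.trait, lo.allele_name,
                        lo.variant_class, lo.cds_notation,
                        *cfields(lo.coord_fca126), *cfields(lo.coord_anams),
                        lo.inheritance, lo.inheritance_source,
                        ",".join(lo.epistasis_tags),
                    ]
                )
                + "\n"
            )


def locus_window(locus: PanelLocus, assembly: str, pad: int = 0) -> tuple[str, int, int]:
    """1-based inclusive interval [start-pad, end+pad] around a locus.

    The start is clamped to 1.  Raises :class:`PanelError` if the locus has no
    coordinates in the requested assembly (the orange locus on Fca126).
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    c = locus.coord(assembly)
    return (c.chrom, max(1, c.start - pad), c.end + pad)


def load_study_genotypes(path: str | Path | None = None):
    """Published per-sample allele depths and genotypes, as a pandas DataFrame.

    Columns: locus_id, sample, ref_depth, alt_depth, genotype, note.  Depth
    columns are nullable integers ('.' rows — SV-evidence loci — become NA).
    """
    import pandas as pd

    path = _data_path("study_genotypes.tsv") if path is None else Path(path)
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["locus_id", "sample", "ref_depth", "alt_depth", "genotype", "note"],
        dtype=str,
    )
    df["note"] = df["note"].fillna("")
    for col in ("ref_depth", "alt_depth"):
        df[col] = pd.to_numeric(df[col].replace(".", None), errors="raise").astype("Int64")
    return df
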