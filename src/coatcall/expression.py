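"""Exon-length-normalised expression: transcript level, TPM, and the
per-gene display transform used for tissue panels.

Given a gene x tissue table of (possibly fractional) read counts and total
exon length per gene, the transcript level of a gene is count / exon_length;
TPM rescales transcript levels so each tissue sums to one million.  The
display transform is log2(TPM + 1) followed by division of each gene's row
by its maximum, giving values in [0, 1] with the top tissue at exactly 1 —
the layout used to compare a gene's expression across tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "compute_tpm",
    "display_transform",
    "exon_lengths_from_gtf",
]


def compute_tpm(counts: pd.DataFrame, exon_lengths: pd.Series) -> pd.DataFrame:
    """TPM per gene and tissue.

    ``counts`` is gene x tissue (non-negative, fractional allowed);
    ``exon_lengths`` gives total exon length (bp) per gene.  A tissue whose
    counts are all zero yields all-zero TPM with a warning.
    """
    lengths = exon_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"exon length missing for genes: {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])[:5]
        raise ValueError(f"exon lengths must be positive; offending genes: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    level = counts.div(lengths, axis=0)
    totals = level.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero tissues: {list(totals.index[zero])}",
                      stacklevel=2)
    safe = totals.replace(0, np.nan)
    tpm = level.div(safe, axis=1) * 1_000_000
    return tpm.fillna(0.0)


def display_transform(tpm: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(log2(TPM+1), per-gene max-normalised) layers.

    Genes with zero TPM everywhere get all-zero display values; otherwise
    each gene's maximum tissue displays exactly 1.
    """
    log2p1 = np.log2(tpm + 1.0)
    row_max = log2p1.max(axis=1)
    display = log2p1.div(row_max.replace(0, np.nan), axis=0).fillna(0.0)
    return log2p1, display


@dataclass
class ExpressionMatrix:
    """Counts with exon lengths and the derived layers, kept in step."""

    counts: pd.DataFrame
    exon_lengths: pd.Series
    transcript_level: pd.DataFrame = field(init=False)
    tpm: pd.DataFrame = field(init=False)
    log2_tpm_plus1: pd.DataFrame = field(init=False)
    display: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.exon_lengths = self.exon_lengths.reindex(self.counts.index)
        self.tpm = compute_tpm(self.counts, self.exon_lengths)
        self.transcript_level = self.counts.div(self.exon_lengths, axis=0)
        self.log2_tpm_plus1, self.display = display_transform(self.tpm)

    def to_dir(self, outdir: str | Path, float_format: str = "%.10g") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t",
                           float_format=float_format)
        self.exon_lengths.to_frame().to_csv(outdir / "exon_lengths.tsv", sep="\t")
        for name in ("transcript_level", "tpm", "log2_tpm_plus1", "display"):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t",
                                       float_format=float_format)

    @classmethod
    def from_dir(cls, indir: str | Path) -> "ExpressionMatrix":
        indir = Path(indir)
        counts = pd.read_csv(indir / "counts.tsv", sep="\t",
                             index_col=0).astype(float)
        lengths = pd.read_csv(indir / "exon_lengths.tsv", sep="\t",
                              index_col=0).iloc[:, 0]
        return cls(counts, lengths)

    def plot_panels(self, genes=None, path: str | Path | None = None):
        """Bar panels of the display layer, one row per gene (optional;
        needs matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        genes = list(genes) if genes is not None else list(self.display.index)
        fig, axes = plt.subplots(len(genes), 1, figsize=(8, 1.2 * len(genes)),
                                 squeeze=False, sharex=True)
        for ax, gene in zip(axes[:, 0], genes):
            ax.bar(self.display.columns, self.display.loc[gene], color="firebrick")
            ax.set_ylabel(gene, rotation=0, ha="right", va="center", fontsize=8)
            ax.set_ylim(0, 1.05)
        axes[-1, 0].tick_params(axis="x", labelrotation=90, labelsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


_GTF_COLUMNS = ["seqname", "source", "feature", "start", "end",
                "score", "strand", "frame", "attributes"]


def _merge_lengths(group: pd.DataFrame) -> int:
    spans = sorted(zip(group["start"], group["end"]))
    total, cur_s, cur_e = 0, None, None
    for s, e in spans:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def exon_lengths_from_gtf(path: str | Path, merge_overlaps: bool = False
                          ) -> pd.Series:
    """Total exon length per gene_id from a standard 9-column GTF.

    By default exon record lengths are summed as annotated (duplicated or
    overlapping exons counted each time); ``merge_overlaps=True`` collapses
    overlapping exon intervals per gene first.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=_GTF_COLUMNS, dtype={"start": int, "end": int})
    exons = df[df["feature"] == "exon"].copy()
    if exons.empty:
        raise ValueError(f"{path}: no exon records")
    gene_ids = exons["attributes"].str.extract(r'gene_id "([^"]+)"')[0]
    if gene_ids.isna().any():
        row = exons.index[gene_ids.isna()][0]
        raise ValueError(f"{path}: exon record without gene_id at row {row}")
    exons["gene_id"] = gene_ids
    if merge_overlaps:
        lengths = exons.groupby("gene_id", sort=True).apply(
            _merge_lengths, include_groups=False)
    else:
        exons["len"] = exons["end"] - exons["start"] + 1
        lengths = exons.groupby("gene_id", sort=True)["len"].sum()
    lengths.name = "exon_length"
    return lengths.astype(int)
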