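"""Built-in genotype descriptions of the two study samples.

The published per-locus depths and genotypes of the CRFK (kidney-line) and
PG-4 (astrocyte-line) donor genomes ship with the package
(``data/study_genotypes.tsv``).  This module turns them into the two object
kinds the pipeline consumes:

* a :class:`~coatcall.synthio.GenotypeSpec` assigning panel alleles to two
  haplotypes, for regenerating synthetic evidence that reproduces the
  published calls, and
* a :class:`~coatcall.phenotype_engine.GenotypeVector` of calls for the
  phenotype engine, including the trans phase of the PG-4 FGF5 compound
  heterozygote (established from read evidence) and the deliberately
  unknown phase of its two LVRN heterozygotes.
"""

from __future__ import annotations

from .genotyper import AlleleDepth, GenotypeCall
from .panel import load_panel, load_study_genotypes, panel_by_id
from .phenotype_engine import GenotypeVector
from .sv_detector import SVCall
from .synthio import GenotypeSpec

__all__ = ["SAMPLES", "study_sample_spec", "study_genotype_vector",
           "genotype_state"]

SAMPLES = ("CRFK", "PG-4")

#: locus pairs with published read-backed phase evidence
_KNOWN_TRANS = {"PG-4": [("FGF5_l_474del", "FGF5_l_475")]}


def genotype_state(genotype: str, allele_name: str) -> str:
    """Map a printed genotype string to hom_ref/het/hom_alt (het strings may
    print the mutant allele on either side)."""
    parts = genotype.split("/")
    if len(parts) != 2:
        raise ValueError(f"unparseable genotype {genotype!r}")
    n_alt = sum(p != "+" for p in parts)
    return {0: "hom_ref", 1: "het", 2: "hom_alt"}[n_alt]


def _rows(sample: str):
    df = load_study_genotypes()
    sub = df[df["sample"] == sample]
    if sub.empty:
        raise ValueError(f"unknown sample {sample!r}; choices: {SAMPLES}")
    return sub


def study_sample_spec(sample: str) -> GenotypeSpec:
    """Two-haplotype allele assignment reproducing a study sample.

    Compound-heterozygous pairs with known trans phase get their alt alleles
    on opposite haplotypes; other het loci put the alt on haplotype 2.
    """
    idx = panel_by_id()
    haplotypes: dict[str, tuple[str, str]] = {}
    trans_pairs = dict(_KNOWN_TRANS.get(sample, []))
    first_of_pair = set(trans_pairs)
    second_of_pair = set(trans_pairs.values())
    for row in _rows(sample).itertuples():
        locus = idx[row.locus_id]
        if locus.is_sv:
            continue
        state = genotype_state(row.genotype, locus.allele_name)
        if state == "hom_ref":
            continue
        if state == "hom_alt":
            haplotypes[row.locus_id] = ("alt", "alt")
        elif row.locus_id in first_of_pair:
            haplotypes[row.locus_id] = ("alt", "ref")
        elif row.locus_id in second_of_pair:
            haplotypes[row.locus_id] = ("ref", "alt")
        else:
            haplotypes[row.locus_id] = ("ref", "alt")
    return GenotypeSpec(haplotypes=haplotypes)


def study_genotype_vector(sample: str) -> GenotypeVector:
    """GenotypeVector of the published calls for one study sample."""
    idx = panel_by_id()
    calls: dict[str, GenotypeCall | SVCall] = {}
    for row in _rows(sample).itertuples():
        locus = idx[row.locus_id]
        state = genotype_state(row.genotype, locus.allele_name)
        if locus.is_sv:
            sv_state = {"hom_ref": "absent", "het": "het",
                        "hom_alt": "hom"}[state]
            evidence = row.note if row.note in (
                "depth_track", "junction_reads") else "longread_insertion"
            evidence = {"depth_track": "depth_ratio"}.get(evidence, evidence)
            calls[row.locus_id] = SVCall(row.locus_id, evidence, sv_state)
        else:
            depth = AlleleDepth(row.locus_id, int(row.ref_depth),
                                int(row.alt_depth))
            notation = {"hom_ref": "+/+",
                        "het": f"+/{locus.allele_name}",
                        "hom_alt": f"{locus.allele_name}/{locus.allele_name}",
                        }[state]
            calls[row.locus_id] = GenotypeCall(row.locus_id, state, depth,
                                               notation)
    phase = {pair: "trans" for pair in _KNOWN_TRANS.get(sample, [])}
    return GenotypeVector(sample_id=sample, calls=calls, phase=phase)
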