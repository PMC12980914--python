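"""Shared builders for phenotype-engine tests."""

from coatcall.genotyper import AlleleDepth, GenotypeCall
from coatcall.phenotype_engine import GenotypeVector
from coatcall.sv_detector import SVCall

TRAITS = ("base_color", "color_modifier", "dilution", "white_pattern",
          "tabby_pattern", "coat_length", "coat_texture", "iris")


def make_call(locus_id, state, allele="x"):
    depth = {"hom_ref": (20, 0), "het": (10, 10), "hom_alt": (0, 20)}[state]
    notation = {"hom_ref": "+/+", "het": f"+/{allele}",
                "hom_alt": f"{allele}/{allele}"}[state]
    return GenotypeCall(locus_id, state, AlleleDepth(locus_id, *depth),
                        notation)


def traits(report):
    return {t: getattr(report, t) for t in TRAITS}


def random_genotype_vector(panel, rng, sample_id="rand"):
    """A random but internally consistent genotype vector: SV loci get SV
    calls, small loci get depth-backed calls, and trans phase is only ever
    asserted between two existing het calls of one gene."""
    calls = {}
    phase = {}
    for lo in panel:
        state = rng.choices(["absent", "hom_ref", "het", "hom_alt"],
                            weights=[0.15, 0.45, 0.25, 0.15])[0]
        if state == "absent":
            continue
        if lo.is_sv:
            calls[lo.locus_id] = SVCall(
                lo.locus_id, "depth_ratio",
                {"hom_ref": "absent", "het": "het", "hom_alt": "hom"}[state])
        else:
            calls[lo.locus_id] = make_call(lo.locus_id, state, lo.allele_name)
    by_gene = {}
    for lo in panel:
        c = calls.get(lo.locus_id)
        if isinstance(c, GenotypeCall) and c.call == "het":
            by_gene.setdefault(lo.gene, []).append(lo.locus_id)
    for gene, lids in by_gene.items():
        if len(lids) >= 2 and rng.random() < 0.5:
            phase[tuple(sorted(lids[:2]))] = "trans"
    sex = rng.choice(["XX", "XY", "unknown"])
    return GenotypeVector(sample_id, calls=calls, sex=sex, phase=phase)
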