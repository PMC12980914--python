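"""Dominance/recessivity/epistasis rules of the phenotype engine."""

import random

import pytest
from helpers import TRAITS, make_call as _call, random_genotype_vector, traits as _traits

from coatcall.genotyper import GenotypeCall
from coatcall.phenotype_engine import GenotypeVector, explain, infer_phenotype
from coatcall.samples import study_genotype_vector
from coatcall.sv_detector import SVCall


def test_kidney_line_donor_phenotype(panel):
    report = infer_phenotype(study_genotype_vector("CRFK"), panel)
    assert _traits(report) == {
        "base_color": "black", "color_modifier": "none", "dilution": "none",
        "white_pattern": "none", "tabby_pattern": "suppressed_solid",
        "coat_length": "long", "coat_texture": "normal", "iris": "non-blue"}


def test_astrocyte_line_donor_phenotype(panel):
    report = infer_phenotype(study_genotype_vector("PG-4"), panel)
    assert _traits(report) == {
        "base_color": "black", "color_modifier": "none", "dilution": "none",
        "white_pattern": "spotting_bicolor",
        "tabby_pattern": "suppressed_solid", "coat_length": "long",
        "coat_texture": "normal", "iris": "non-blue"}
    assert any("phase unknown" in n for n in report.notes)


def test_all_reference_vector_maps_to_defaults(panel):
    report = infer_phenotype(GenotypeVector("ref_cat"), panel)
    assert _traits(report) == {
        "base_color": "black", "color_modifier": "none", "dilution": "none",
        "white_pattern": "none", "tabby_pattern": "mackerel_default",
        "coat_length": "short", "coat_texture": "normal", "iris": "non-blue"}
    assert report.justifications == []
    assert len(report.assumed_loci) == 31


def test_full_white_masks_base_colour_and_opens_blue_iris(panel):
    gv = GenotypeVector("w", calls={
        "KIT_wW": SVCall("KIT_wW", "longread_insertion", "het"),
        "TYRP1_b": _call("TYRP1_b", "hom_alt", "b")})
    report = infer_phenotype(gv, panel)
    assert report.white_pattern == "full_white"
    assert report.base_color == "masked"
    assert report.iris == "blue_or_odd_possible"


def test_nonagouti_masks_expressed_tabby_genotype(panel):
    gv = GenotypeVector("s", calls={
        "ASIP_a": _call("ASIP_a", "hom_alt", "a"),
        "LVRN_tb_2522": _call("LVRN_tb_2522", "hom_alt", "t^b")})
    report = infer_phenotype(gv, panel)
    assert report.tabby_pattern == "suppressed_solid"
    assert any("masked by nonagouti" in rule
               for _, _, rule in report.justifications)
    # without nonagouti the same genotype expresses blotched
    gv2 = GenotypeVector("s2", calls={
        "LVRN_tb_2522": _call("LVRN_tb_2522", "hom_alt", "t^b")})
    assert infer_phenotype(gv2, panel).tabby_pattern == "blotched"


def test_dominant_spotting_fires_from_het(panel):
    gv = GenotypeVector("sp", calls={
        "KIT_wS": SVCall("KIT_wS", "longread_insertion", "het")})
    report = infer_phenotype(gv, panel)
    assert report.white_pattern == "spotting_bicolor"
    assert report.iris == "non-blue"


def test_blue_iris_insertion_dominant(panel):
    gv = GenotypeVector("b", calls={
        "PAX3_DBE_Cel": SVCall("PAX3_DBE_Cel", "junction_reads", "present")})
    assert infer_phenotype(gv, panel).iris == "blue"


@pytest.mark.parametrize("sex, state, base, note_part", [
    ("XY", "het", "orange", None),
    ("XX", "hom_alt", "orange", None),
    ("XX", "het", "black", "tortoiseshell"),
    ("unknown", "het", "black", "unknown sex"),
])
def test_x_linked_orange_by_sex(panel, sex, state, base, note_part):
    gv = GenotypeVector("o", sex=sex, calls={
        "ARHGAP36_o": SVCall("ARHGAP36_o", "depth_ratio",
                             {"het": "het", "hom_alt": "hom"}[state])})
    report = infer_phenotype(gv, panel)
    assert report.base_color == base
    if note_part:
        assert any(note_part in n for n in report.notes)


def test_unphased_double_het_does_not_express(panel):
    gv = GenotypeVector("u", calls={
        "FGF5_l_474del": _call("FGF5_l_474del", "het", "l"),
        "FGF5_l_475": _call("FGF5_l_475", "het", "l")})
    report = infer_phenotype(gv, panel)
    assert report.coat_length == "short"
    assert any("phase unknown" in n for n in report.notes)
    # with established trans phase the same calls express long fur
    gv.phase = {("FGF5_l_474del", "FGF5_l_475"): "trans"}
    assert infer_phenotype(gv, panel).coat_length == "long"


def test_contradictory_call_entry_names_locus(panel):
    with pytest.raises(ValueError, match="MLPH_d"):
        GenotypeVector("bad", calls={"MLPH_d": _call("ASIP_a", "het")})


def test_carrier_invariance_and_masks_over_random_vectors(panel):
    """A single het call at a recessive locus never changes any trait, and
    the two documented masks always hold, over 300 random vectors."""
    rng = random.Random(20240901)
    recessive = [lo for lo in panel if lo.inheritance == "recessive"]
    for _ in range(300):
        gv = random_genotype_vector(panel, rng)
        report = infer_phenotype(gv, panel)
        # mask rules
        if gv.zygosity("ASIP_a")[0] == "hom_alt":
            assert report.tabby_pattern == "suppressed_solid"
        if gv.zygosity("KIT_wW")[0] in ("het", "hom_alt", "present"):
            assert report.base_color == "masked"
            assert report.white_pattern == "full_white"
        # recessive traits never fire from a lone het
        if gv.zygosity("MLPH_d")[0] != "hom_alt":
            assert report.dilution == "none"
        # carrier invariance: add a het at a recessive locus not yet called
        candidates = [lo for lo in recessive if lo.locus_id not in gv.calls]
        if not candidates:
            continue
        lo = rng.choice(candidates)
        gv2 = GenotypeVector(gv.sample_id, calls=dict(gv.calls), sex=gv.sex,
                             phase=dict(gv.phase))
        gv2.calls[lo.locus_id] = _call(lo.locus_id, "het", lo.allele_name)
        assert _traits(infer_phenotype(gv2, panel)) == _traits(report)


def test_rule_evaluation_independent_of_call_order(panel):
    gv = study_genotype_vector("PG-4")
    shuffled = dict(reversed(list(gv.calls.items())))
    gv2 = GenotypeVector(gv.sample_id, calls=shuffled, phase=dict(gv.phase))
    assert _traits(infer_phenotype(gv, panel)) == _traits(infer_phenotype(gv2, panel))


def test_explanations_cite_rules_and_defaults(panel):
    crfk = explain(infer_phenotype(study_genotype_vector("CRFK"), panel))
    assert "masked by nonagouti" in crfk
    default = explain(infer_phenotype(GenotypeVector("ref"), panel))
    assert all("[default/assumed]" in line
               for line in default.splitlines() if line.startswith(tuple(TRAITS)))
    dilute = GenotypeVector("d", calls={"MLPH_d": _call("MLPH_d", "hom_alt", "d")})
    assert "MLPH_d" in explain(infer_phenotype(dilute, panel))
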