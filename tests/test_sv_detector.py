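"""Depth-ratio, split-read junction and long-read insertion evidence."""

import numpy as np
import pytest

from coatcall.sv_detector import (DepthTrack, call_kit_insertion,
                                  classify_long_read, depth_ratio_test,
                                  dual_mapping_reads, insertion_class)
from coatcall.synthio import (SynthConfig, kit_region,
                              simulate_depth_track,
                              simulate_junction_alignments,
                              simulate_long_reads)


@pytest.mark.parametrize("genotype, ratio, verdict", [
    ("none", 1.0, "absent"), ("het", 0.5, "het"), ("hom", 0.0, "hom"),
])
def test_noise_free_depth_ratio(genotype, ratio, verdict):
    track, region = simulate_depth_track(3000, 3000, 24.0, genotype,
                                         noise=0.0, seed=1)
    call = depth_ratio_test(track, region, locus_id="KIT_wSal")
    assert call.stats["ratio"] == pytest.approx(ratio)
    assert call.genotype == verdict


def test_zero_depth_flanks_are_uninformative():
    track = DepthTrack("B1", 1, np.zeros(300))
    with pytest.raises(ValueError, match="uninformative"):
        depth_ratio_test(track, (101, 200))


def test_deletion_genotype_recovery_under_noise():
    genotypes = ["none", "het", "hom"]
    correct = 0
    for rep in range(30):
        g = genotypes[rep % 3]
        track, region = simulate_depth_track(5000, 5000, 20 + rep % 6, g,
                                             noise=0.3, seed=100 + rep)
        if depth_ratio_test(track, region).genotype == {
                "none": "absent", "het": "het", "hom": "hom"}[g]:
            correct += 1
    assert correct >= 29


def test_wild_type_reads_give_no_junction_support(clean_config):
    vs_target, vs_insert, _ = simulate_junction_alignments(0, 40, clean_config)
    call = dual_mapping_reads(vs_target, vs_insert, locus_id="PAX3_DBE_Cel")
    assert call.genotype == "absent"
    assert call.stats["n_supporting"] == 0


def test_planted_junction_reads_detected_and_match_truth(clean_config):
    vs_target, vs_insert, truth = simulate_junction_alignments(
        8, 40, clean_config)
    call = dual_mapping_reads(vs_target, vs_insert, locus_id="PAX3_DBE_Cel")
    assert call.genotype == "present"
    assert call.stats["supporting_reads"] == sorted(truth["junction_reads"])


def test_junction_specificity_against_unrelated_insert(clean_config):
    vs_target, _, _ = simulate_junction_alignments(0, 40, clean_config)
    _, other_insert, _ = simulate_junction_alignments(
        6, 0, clean_config, insert_name="RD114-LTR")
    call = dual_mapping_reads(vs_target, other_insert)
    assert call.stats["n_supporting"] == 0
    assert call.genotype == "absent"


def test_empty_inputs_reported_absent_with_warning_reason():
    call = dual_mapping_reads([], [])
    assert call.genotype == "absent"
    assert call.reason == "empty inputs"


def test_long_read_classification_agrees_with_truth(clean_config):
    reads, truth, region = simulate_long_reads(4, 2, clean_config)
    for (name, seq), t in zip(reads, truth):
        v = classify_long_read((name, seq), region.flank_left,
                               region.flank_right, region.insert)
        if t["has_insertion"]:
            assert v.verdict == "insertion-containing"
            assert v.measured_length == t["insertion_length"] == 7400
        else:
            assert v.verdict == "reference-like"
            assert v.measured_length == 0


def test_short_insertion_below_threshold_is_reference_like():
    config = SynthConfig(insertion_sequence_length=100, rng_seed=3,
                         base_error_rate=0.0)
    reads, _, region = simulate_long_reads(1, 0, config)
    v = classify_long_read(reads[0], region.flank_left, region.flank_right,
                           region.insert)
    assert v.verdict == "reference-like"
    assert v.measured_length == 100


def test_unrelated_sequence_is_unaligned(clean_config):
    region = kit_region(clean_config)
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), size=5000))
    v = classify_long_read(junk, region.flank_left, region.flank_right,
                           region.insert)
    assert v.verdict == "unaligned"


def test_classification_tolerates_base_errors():
    config = SynthConfig(base_error_rate=0.002, rng_seed=4)
    reads, truth, region = simulate_long_reads(4, 2, config)
    for (name, seq), t in zip(reads, truth):
        v = classify_long_read((name, seq), region.flank_left,
                               region.flank_right, region.insert)
        expected = "insertion-containing" if t["has_insertion"] else "reference-like"
        assert v.verdict == expected


def test_sample_level_call_from_verdict_mix(clean_config):
    reads, _, region = simulate_long_reads(4, 2, clean_config)
    verdicts = [classify_long_read(r, region.flank_left, region.flank_right,
                                   region.insert) for r in reads]
    call = call_kit_insertion(verdicts)
    assert call.genotype == "het"
    assert call.stats["n_insertion"] == 4 and call.stats["n_aligned"] == 6

    ref_reads, _, _ = simulate_long_reads(0, 4, clean_config)
    ref_verdicts = [classify_long_read(r, region.flank_left,
                                       region.flank_right, region.insert)
                    for r in ref_reads]
    assert call_kit_insertion(ref_verdicts).genotype == "absent"
    assert call_kit_insertion([]).genotype == "no_call"
    assert call_kit_insertion(ref_verdicts[:1]).genotype == "ambiguous"


@pytest.mark.parametrize("length, cls", [
    (400, "LTR-class"), (7400, "full-element"), (5000, "ambiguous"),
])
def test_insertion_length_classes(length, cls):
    assert insertion_class(length) == cls
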