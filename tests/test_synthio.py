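"""Synthetic-data generators: edits, reads, depth tracks, counts."""

import numpy as np
import pytest

from coatcall.panel import PanelError
from coatcall.synthio import (GenotypeSpec, SynthConfig, kit_region,
                              make_haplotypes, simulate_counts,
                              simulate_depth_track, simulate_long_reads,
                              simulate_short_reads)


def test_ref_ref_haplotypes_match_reference(idx):
    pair = make_haplotypes(GenotypeSpec(), [idx["TYR_cs"]])
    assert pair.hap1.seq == pair.reference
    assert pair.hap2.seq == pair.reference


def test_single_base_deletion_shortens_one_window(idx):
    spec = GenotypeSpec({"MLPH_d": ("ref", "alt")})
    pair = make_haplotypes(spec, [idx["MLPH_d"]])
    assert len(pair.hap1.seq) == len(pair.reference)
    assert len(pair.hap2.seq) == len(pair.reference) - 1


def test_compound_het_edits_never_co_occur(idx):
    spec = GenotypeSpec({"FGF5_l_474del": ("alt", "ref"),
                         "FGF5_l_475": ("ref", "alt")})
    pair = make_haplotypes(spec, [idx["FGF5_l_474del"], idx["FGF5_l_475"]])
    assert [e[0] for e in pair.hap1.edits] == ["DEL"]
    assert [e[0] for e in pair.hap2.edits] == ["SNV"]


def test_spec_with_unknown_locus_rejected(idx):
    spec = GenotypeSpec({"NOT_A_LOCUS": ("ref", "alt")})
    with pytest.raises(PanelError, match="NOT_A_LOCUS"):
        make_haplotypes(spec, [idx["MLPH_d"]])


def test_error_free_reads_match_reference(idx, clean_config):
    pair = make_haplotypes(GenotypeSpec(), [idx["TYR_cs"]], pad=300)
    reads = simulate_short_reads(pair, clean_config)
    assert reads
    for read in reads:
        offset = read.pos - pair.window_start
        assert read.seq == pair.reference[offset: offset + len(read.seq)]
        assert read.cigar == f"{len(read.seq)}M"


def test_coverage_close_to_requested_depth(idx):
    config = SynthConfig(mean_depth=20.0, base_error_rate=0.0, rng_seed=2)
    pair = make_haplotypes(GenotypeSpec(), [idx["TYR_cs"]], pad=500)
    window_len = pair.window_end - pair.window_start + 1
    total_bases = sum(len(r.seq) for r in simulate_short_reads(pair, config))
    assert abs(total_bases - 20 * window_len) <= 2 * config.read_length


def test_read_simulation_deterministic_under_seed(idx, clean_config):
    pair = make_haplotypes(GenotypeSpec({"MLPH_d": ("ref", "alt")}),
                           [idx["MLPH_d"]])
    lines = [r.to_sam_line() for r in simulate_short_reads(pair, clean_config)]
    again = [r.to_sam_line() for r in simulate_short_reads(pair, clean_config)]
    assert lines == again


def test_long_reads_carry_planted_insertion(clean_config):
    reads, truth, region = simulate_long_reads(4, 2, clean_config)
    assert len(reads) == 6
    with_ins = [seq for _, seq in reads[:4]]
    assert all(region.insert in seq for seq in with_ins)
    assert all(t["insertion_length"] == 7400 for t in truth[:4])


def test_insertion_free_long_reads_share_no_insert_kmers(clean_config):
    reads, _, region = simulate_long_reads(0, 4, clean_config)
    probes = {region.insert[i: i + 31] for i in range(0, 600, 31)}
    for _, seq in reads:
        assert not any(p in seq for p in probes)


def test_long_reads_require_at_least_one_read(clean_config):
    with pytest.raises(ValueError):
        simulate_long_reads(0, 0, clean_config)


def test_configurable_insertion_length():
    config = SynthConfig(insertion_sequence_length=9_000, rng_seed=0,
                         base_error_rate=0.0)
    _, truth, region = simulate_long_reads(1, 0, config)
    assert len(region.insert) == 9_000
    assert truth[0]["insertion_length"] == 9_000


@pytest.mark.parametrize("genotype, expected_region_mean",
                         [("none", 23.0), ("het", 11.5), ("hom", 0.0)])
def test_noise_free_depth_track_scaling(genotype, expected_region_mean):
    track, (rs, re) = simulate_depth_track(2000, 1000, 23.0, genotype,
                                           noise=0.0, seed=5)
    region = track.slice(rs, re)
    flank = track.slice(track.start, rs - 1)
    assert region.mean() == pytest.approx(expected_region_mean)
    assert flank.mean() == pytest.approx(23.0)


def test_depth_track_dispersion_around_baseline():
    track, (rs, re) = simulate_depth_track(5000, 5000, 23.0, "none",
                                           noise=0.2, seed=5)
    assert track.depths.min() >= 0
    assert track.slice(rs, re).mean() == pytest.approx(23.0, rel=0.1)
    # dispersed: variance well above Poisson
    assert track.depths.var() > 2 * 23.0


def test_counts_are_deterministic_nonnegative_integers():
    counts, lengths = simulate_counts(30, 5, seed=9)
    counts2, _ = simulate_counts(30, 5, seed=9)
    assert counts.equals(counts2)
    assert (counts.to_numpy() >= 0).all()
    assert np.issubdtype(counts.to_numpy().dtype, np.integer)
    assert (lengths > 0).all()
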