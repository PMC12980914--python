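"""The three structural-variant evidence types on synthetic data.

1. depth-ratio test over a planted heterozygous deletion (the salmiak /
   orange style of evidence),
2. split-read junction support for an LTR insertion (the blue-iris PAX3
   style), and
3. long-read classification of a multi-kb insertion at the KIT intron-1
   junction (the white-spotting FERV1 style).
"""

from coatcall import (SynthConfig, call_kit_insertion, classify_long_read,
                      depth_ratio_test, dual_mapping_reads)
from coatcall.synthio import (simulate_depth_track,
                              simulate_junction_alignments,
                              simulate_long_reads)

# 1. depth ratio: region depth / pooled flank depth
track, region = simulate_depth_track(5_000, 5_000, 23.0, "het",
                                     noise=0.2, seed=3)
call = depth_ratio_test(track, region, locus_id="KIT_wSal")
print(f"depth ratio r={call.stats['ratio']:.3f} -> {call.genotype}")
# r near 0.5 = one of two copies deleted (heterozygous).

# 2. split reads across an LTR/intron junction, matched by read name
config = SynthConfig(rng_seed=3)
vs_target, vs_insert, truth = simulate_junction_alignments(8, 40, config)
call = dual_mapping_reads(vs_target, vs_insert, locus_id="PAX3_DBE_Cel")
print(f"junction support: {call.stats['n_supporting']} reads -> {call.genotype}")
# every read aligning to both the insert and the intron window is one
# independent piece of insertion evidence.

# 3. long reads through the KIT junction: 4 of 6 carry a 7.4 kb element
reads, _, region = simulate_long_reads(4, 2, SynthConfig(rng_seed=3))
verdicts = [classify_long_read(r, region.flank_left, region.flank_right,
                               region.insert) for r in reads]
call = call_kit_insertion(verdicts)
print(f"KIT insertion: {call.stats['n_insertion']}/{call.stats['n_aligned']} "
      f"reads, min length "
      f"{min(call.stats['insertion_lengths'])/1000:.1f} kbp -> {call.genotype}")
# a mixture of insertion-bearing and clean junction reads = heterozygous
# insertion; all lengths exceed 7 kbp, i.e. the full element, the
# white-spotting allele (an LTR-only insertion would be ~10x shorter).
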