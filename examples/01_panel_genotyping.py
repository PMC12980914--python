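"""Genotype a dilution-carrier pileup at the MLPH locus.

Builds an error-free synthetic read set with 15 reference-supporting and 4
deletion-supporting reads over the MLPH c.83del window — the allele balance
observed in the CRFK cell-line genome — counts allele support, and calls the
diploid genotype.
"""

from coatcall import SynthConfig, call_genotype, count_alleles, panel_by_id
from coatcall.synthio import GenotypeSpec, make_haplotypes, simulate_short_reads

idx = panel_by_id()
locus = idx["MLPH_d"]

spec = GenotypeSpec({"MLPH_d": ("ref", "alt")})
pair = make_haplotypes(spec, [locus], pad=300)
config = SynthConfig(base_error_rate=0.0, rng_seed=1)
reads = simulate_short_reads(pair, config, reads_per_hap=(15, 4),
                             focus_loci=[locus])

depth = count_alleles(reads, locus)
call = call_genotype(depth, locus.allele_name)

print(f"locus {locus.locus_id} ({locus.gene} {locus.cds_notation})")
print(f"ref_depth={depth.ref_depth} alt_depth={depth.alt_depth} "
      f"other={depth.other_depth}")
print(f"call={call.call} notation={call.notation}")
# 15:4 clears the 3-read / 15% support thresholds for both alleles, so the
# cat is a heterozygous dilution carrier (+/d): its coat is NOT dilute,
# because the dilute allele only expresses when homozygous.
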