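"""Infer the donor-cat phenotypes of the two study cell lines.

The published per-locus genotypes of the CRFK (kidney) and PG-4 (astrocyte)
cell-line genomes ship with the package; the rule engine folds dominance,
recessivity and the two epistatic masks (full white over base colour,
nonagouti over tabby pattern) into a structured report with per-trait
justifications.
"""

from coatcall import explain, infer_phenotype
from coatcall.samples import study_genotype_vector

for sample in ("CRFK", "PG-4"):
    report = infer_phenotype(study_genotype_vector(sample))
    print(f"=== {sample} donor ===")
    print(explain(report))
    print()
# CRFK: long black unstriped fur, non-blue irises — the blotched-tabby
# genotype is masked by nonagouti, and the heterozygous dilution allele is a
# silent carrier. PG-4: adds dominant white spotting from the heterozygous
# KIT FERV1 insertion; the two unphased LVRN heterozygotes are reported with
# "phase unknown" rather than assumed compound.
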