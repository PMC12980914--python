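# coatcall

Panel genotyping and coat/iris phenotype inference for domestic cats
(*Felis catus*) from aligned sequencing reads.

A cat's visible phenotype — coat colour, white patterning, tabby pattern,
coat length, coat texture and iris colour — is largely controlled by a small
set of well-characterised genes: *TYR*, *TYRP1*, *MC1R*, *KIT*, *ARHGAP36*,
*MLPH*, *ASIP*, *LVRN*, *DKK4*, *FGF5*, *KRT71*, *LPAR6* and *PAX3*.
`coatcall` is for anyone who has whole-genome sequencing of a cat (or of a
feline cell line whose donor's appearance is unknown) and wants a defensible,
fully-justified phenotype prediction from it. It implements the complete
inference chain:

* **panel** — a versioned table of the causal alleles at the 13 genes, with
  1-based coordinates in both current reference assemblies
  (F.catus_Fca126_mat1.0 and AnAms1.0) and inheritance annotations;
* **genotyper** — allele-depth counting at each panel locus (a read votes
  for the alternate allele only when its bases and gap structure reproduce
  the edit exactly), threshold-based diploid calling, and read-backed
  phasing that resolves adjacent heterozygous variants into cis or trans
  (compound heterozygote) configurations;
* **sv_detector** — the three structural-variant evidence types the panel
  needs: large deletions by a depth ratio *r* = mean(region)/mean(flanks)
  (*r*≈1 absent, ≈0.5 heterozygous, ≈0 homozygous), LTR insertions by reads
  mapping to both the insert and the target intron, and the multi-kb
  endogenous-retrovirus insertion in *KIT* intron 1 by k-mer-anchored
  long-read classification with a measured insertion length;
* **phenotype_engine** — a dominance/recessivity/epistasis rule table
  producing a structured report with a per-trait justification, including
  the two classical masks (dominant white over base colour, nonagouti over
  tabby pattern) and conservative handling of unphased double heterozygotes;
* **expression** — exon-length-normalised transcript levels and TPM
  (per-tissue sums of 10⁶) with the log2(TPM+1), per-gene max-normalised
  display transform;
* **synthio** — a seeded generator for every input type (diploid haplotype
  windows, 150 bp paired-end reads, tens-of-kb long reads with planted
  insertions, negative-binomial depth tracks, count tables), so the whole
  pipeline is testable without any sequencing data.

## Worked example

Phase the two adjacent *FGF5* long-fur variants of a compound heterozygote
(`examples/02_compound_het_phasing.py`):

```python
from coatcall import SynthConfig, panel_by_id, phase_pair
from coatcall.synthio import GenotypeSpec, make_haplotypes, simulate_short_reads

idx = panel_by_id()
a, b = idx["FGF5_l_474del"], idx["FGF5_l_475"]
spec = GenotypeSpec({a.locus_id: ("alt", "ref"), b.locus_id: ("ref", "alt")})
pair = make_haplotypes(spec, [a, b], pad=300)
reads = simulate_short_reads(pair, SynthConfig(base_error_rate=0.0, rng_seed=2),
                             reads_per_hap=(7, 13), focus_loci=[a, b])
print(phase_pair(reads, a, b))
```

prints

```
FGF5_l_474del: 13:7 -> +/l
FGF5_l_475: 7:13 -> +/l
phase: trans (A-only=7, B-only=13, both=0)
```

Seven reads carry only the deletion, thirteen only the substitution, none
carry both: the variants sit on opposite haplotypes (trans), so the cat is a
compound heterozygote for two loss-of-function *FGF5* alleles and has long
fur, despite being homozygous for neither variant.

The other examples cover pileup genotyping of a dilution carrier
(`01`), the three structural-variant evidence types (`03`), full phenotype
reports with per-trait justifications for the two bundled cell-line donor
genotypes (`04`), and TPM layers (`05`). A thin CLI wraps the same
functions: `coatcall report --sample PG-4 --outdir out --seed 1` chains
simulation → genotyping → SV detection → phenotype into one JSON.

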