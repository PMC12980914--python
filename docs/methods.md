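# Methods

## The inference problem

Given whole-genome alignments of a domestic cat, predict its coat colour,
white patterning, tabby pattern, coat length, coat texture and iris colour.
The causal variation at the 13 genes involved spans every evidence class a
short-read pipeline must handle: SNVs and small indels (genotyped from
pileups), a 163 bp replacement wider than a read, two large deletions
(95 kb between *KIT* and *KDR*, the salmiak allele; 5 kb in *ARHGAP36*
intron 1, the X-linked orange allele), two LTR insertions in *PAX3* intron 4
(blue iris), and the FERV1 endogenous-retrovirus insertion in *KIT* intron 1
whose length distinguishes two alleles (full element → white spotting;
LTR-only → full white). The package genotypes each class with the
appropriate evidence and folds the calls through a genetic rule table.

## Panel encoding

Coordinates are stored 1-based inclusive in both assemblies, exactly as
printed in the curated sources; any half-open arithmetic is internal.
The orange locus has no Fca126 coordinates because the maternal Fca126
haplotype itself carries the deletion; that locus is only addressable on
AnAms1.0. Inheritance annotations carry a provenance column (`study` when
the curating study states the mode, `external` when it comes from the
primary allele literature — salmiak recessive, DKK4 ticked dominant; the
phenotype engine flags traits derived from external annotations). The
compound rexing allele of *KRT71* (an 81 bp deletion plus two small
insertions printed as one allele) is modelled by its discriminating 81 bp
replacement; the full notation is retained in the row. One printed AnAms1.0
coordinate for that allele is internally inconsistent with its CDS span and
was normalised to the 81 bp interval mirroring the Fca126 row.

## Allele counting and calling

A read votes **alt** only when its aligned bases and gap structure reproduce
the panel edit exactly (the full deletion span as a D operation, the full
inserted bases, the full replacement), **ref** only when it matches the
reference allele across the edit footprint plus one anchor base per side,
and **other** otherwise. Reads must span the footprint to vote, with one
deliberate relaxation: for the 163 bp mocha replacement no 150 bp read can
span the reference footprint, so there a read votes ref when it crosses
either edit boundary and matches the reference over its whole overlap.
"Other" reads are excluded from the call denominator and reported
separately, since the sources report depths for the two alleles only.

Diploid calls need `min_total`=5 informative reads; an allele is supported
at `min_allele_reads`=3 and `min_allele_fraction`=0.15. The sources print
depths and calls but no rule; these thresholds are the package's own,
chosen so the published depth pairs — including 15:4 and 5:3
heterozygotes — all reproduce, and they are configurable.

Phasing classifies reads spanning two footprints into A-only / B-only /
both / neither. Trans needs both single-variant classes at ≥3 reads and at
most `max_both`=0 dual reads (the published compound heterozygote partitions
cleanly at 7/13/0; raise `max_both` for noisy data). Pairs no read can span
return `unknown` with reason "no spanning reads" — the expected outcome for
the two *LVRN* variants ~59 kb apart.

## Structural variants

*Depth ratio.* r = mean depth inside the candidate region over the pooled
mean of the two adjacent equal-length flanks. Genotype thresholds
(absent ≥0.8, het 0.3–0.7, hom ≤0.2, otherwise ambiguous) are symmetric
around the copy-number expectations 1.0/0.5/0.0; the sources report only the
qualitative absence of coverage declines, so the numbers are package
defaults, configurable on the CLI.

*Junction reads.* Insertion support = reads whose name appears both in the
alignment to the insert sequence and inside the target window (single split
reads and read pairs both qualify; each name counts once). Presence needs
`min_support`=2; heterozygous versus homozygous is not attempted from this
evidence.

*Long reads.* Instead of an external aligner the classifier anchors each
read with exact 31-mers from the two reference flanks (stepping up to eight
anchors away from the junction, so scattered base errors cost only a known
offset that is corrected for). Measured insertion length = inter-anchor span
in the read minus the reference flank-to-flank distance; the inserted span
must also share ≥30% of 15-mers with the insert probe. A read is
insertion-containing at ≥7,000 bp measured length (the full element exceeds
7 kb); measured lengths under 2 kb are classed LTR-scale (the full-white
allele), an in-between length is flagged ambiguous — the 2 kb boundary is a
package choice at the typical LTR scale. Sample-level genotype: all aligned
reads insertion-containing (n≥2) → hom, none → absent, both classes → het,
a single aligned read → ambiguous.

## Phenotype rules

Rules read only the genotype vector; traits are independent except two
documented masks (full white masks base-colour reporting; nonagouti masks
tabby expression, with masked genotypes still cited in the justification).
Recessive alleles express from a homozygous call or an **established trans**
compound heterozygote; two unphased heterozygotes are reported "phase
unknown" and do not express — exactly the conservative treatment the *LVRN*
double heterozygote requires, and the reason a lone carrier call can never
change a report (carrier invariance, property-tested). The dominant alleles
(*KIT* insertions, *PAX3* insertions, DKK4 ticked) fire from a single copy.
X-linked orange is resolved by sex; with unknown sex the report carries a
conditional note instead of a guess. White spotting reports non-blue irises
with an explicit "less common" caveat rather than a probability;
colourpoint combined with white patterning is flagged as an unmodelled
interaction and the traits are reported independently.

## Expression

Transcript level = count / total exon length; TPM rescales each tissue to
10⁶; the display transform is log2(TPM+1) divided per gene by its maximum.
Fractional counts are accepted (multi-overlap fractional counting produces
them). "Total exon length" from a GTF sums exon records per `gene_id`
without merging overlaps by default, since the upstream description is
ambiguous on merging; `merge_overlaps=True` collapses intervals first.
All-zero tissues give zero TPM with a warning rather than an error.

## Synthetic data

The generator emulates the study conditions: 150 bp paired-end reads at
~23× (the sequenced genomes averaged ≈23.5×), uniform independent base
errors (default 10⁻³), long reads of tens of kb, a planted insert of
7,400 bp (> 7 kb, matching the detected element), and per-base depths that
are negative-binomially dispersed (variance = m + noise·m², noise=0 exact)
scaled ×1/×0.5/×0 for absent/het/hom deletions. Reference windows and the
pseudo-FERV1/LTR inserts are fixed pseudo-random sequences keyed on the
genomic interval or fixture name — bundled fixtures in code form — with
panel SNV reference bases forced, and edits placed at window midpoints.
Detection logic never depends on the specific insert content, only on the
given probe. Not emulated: base-quality profiles, GC bias, alignment
ambiguity in repeats, real retroviral sequence. Passing tests therefore
demonstrate the correctness of the counting, phasing, classification and
rule logic under the stated noise models, not robustness to real-data
alignment artefacts.

Pinned-read mode places each read uniformly among the placements that span
the voting footprint of the focus loci, so a requested ref:alt composition
is reproduced exactly; coverage mode samples fragments (≈380±25 bp insert)
uniformly over the window at the requested fold-coverage.

Problem sizes used by the test suite and acceptance script are desk-scale by
design: per-locus windows of a few hundred bp to a few kb, 20-read phasing
sets, six long reads, 5 kb deletion regions with 200 replicate tracks, and
count matrices of a few hundred genes — the smallest sizes at which each
statistical property is meaningfully exercised.

## Known limitations

* No general liftover: only the stored coordinate pairs address the two
  assemblies.
* Only panel-targeted genotyping — no variant discovery, no genome-wide SV
  scan, no breakpoint refinement.
* Junction evidence cannot distinguish het from hom insertions.
* The rule engine is deterministic and categorical; it does not model
  penetrance or probabilistic traits.
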