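"""TPM-normalise a gene x tissue count table and build display layers.

Counts are divided by total exon length (transcript level), rescaled so each
tissue sums to one million (TPM), then transformed to log2(TPM+1) and
normalised per gene by the maximum tissue — the layout used to compare one
gene's expression profile across tissues.
"""

from coatcall import ExpressionMatrix
from coatcall.synthio import simulate_counts

counts, exon_lengths = simulate_counts(n_genes=12, n_tissues=6, seed=5)
em = ExpressionMatrix(counts.astype(float), exon_lengths)

print("per-tissue TPM sums (should all be 1,000,000):")
print(em.tpm.sum(axis=0).round(3).to_string())
gene = em.tpm.index[0]
print(f"\n{gene}: TPM per tissue")
print(em.tpm.loc[gene].round(1).to_string())
print(f"\n{gene}: display values (max tissue = 1.0)")
print(em.display.loc[gene].round(3).to_string())
# the display row divides log2(TPM+1) by its per-gene maximum, so the most
# expressing tissue reads exactly 1 and the others are fractions of it.
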