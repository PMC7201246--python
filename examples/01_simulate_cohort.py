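"""Simulate a 10-patient cohort and look at its mutation-spectrum structure.

The generator draws each patient's mutated genes from a shared Zipf-like
popularity law over a 12000-gene pool, so a few genes (TP53/TTN/MUC16-like)
recur across patients while most mutations are private — the structure that
motivates per-patient panels in the first place.
"""

from collections import Counter

from icptrack import SimParams, simulate_cohort

cohort = simulate_cohort(SimParams(n_patients=10, seed=1))

counts = {pid: len(df) for pid, df in cohort.variants.items()}
print(f"mutated genes per patient: min={min(counts.values())}, max={max(counts.values())}")

gene_freq = Counter(g for genes in cohort.spectra(retained=False).values() for g in genes)
recurrent = [g for g, c in gene_freq.items() if c > 5]
print(f"gene union: {len(gene_freq)}; mutated in >half the cohort: {sorted(recurrent)}")
print(f"scenarios: {cohort.scenarios}")
# A large union with only a handful of recurrent genes means any fixed gene
# panel can cover only a sliver of each patient's mutations.
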