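"""Apply the somatic retention rules, compute TMB and call clonality.

Variants in segmental duplications with VAF < 0.2 or with population
frequency > 5% are excluded; nonsynonymous SNVs need VAF > 3% (1% at
hotspots). Clonality uses the exact binomial 95% CI of the VAF mapped to a
cancer cell fraction: subclonal when the upper CCF bound is below 1.
"""

from icptrack import SimParams, call_clonality, compute_tmb, filter_variants, simulate_mutation_spectra

variants = simulate_mutation_spectra(SimParams(seed=1))["P01"]
retained, counts = filter_variants(variants, return_counts=True)
print(f"filter: {counts}")
print(f"TMB: {compute_tmb(retained, coding_mb=38.0):.2f} nonsynonymous SNVs / Mb")

for alt, total in [(5, 100), (50, 100)]:
    c = call_clonality(alt, total)
    print(
        f"alt={alt}/{total}: CCF={c.ccf:.2f} [{c.ccf_low:.3f}, {c.ccf_high:.3f}] -> {c.label}"
    )
# A 5% VAF at 100x is confidently subclonal (upper CCF bound ~0.23), while a
# 50% VAF is consistent with a clonal diploid heterozygous mutation.
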