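"""Design an individually customized panel (ICP) from predicted neoepitopes.

Candidates below 500 nM predicted IC50 count as binders; the panel takes the
top 30 binder variants by affinity, or — for patients with fewer than 20
binders — all of them padded with the highest-VAF mutations up to 20 loci.
"""

from icptrack import (
    SimParams,
    coverage_fraction,
    design_panel,
    filter_binders,
    filter_variants,
    simulate_mutation_spectra,
    simulate_neoepitopes,
)

params = SimParams(seed=1)
variants = filter_variants(simulate_mutation_spectra(params)["P01"])
candidates = simulate_neoepitopes(variants, params)
binders = filter_binders(candidates, threshold_nm=500.0)
print(f"{len(candidates)} epitope candidates, {len(binders)} strong binders (<500 nM)")

panel = design_panel(binders, variants, patient_id="P01")
panel.coverage_fraction = coverage_fraction(panel, candidates)
n_neo = (panel.loci["source"] == "neoantigen").sum()
print(f"panel: {len(panel)} loci ({n_neo} neoantigen, {len(panel) - n_neo} VAF filler)")
print(f"repertoire coverage: {panel.coverage_fraction:.1%} of predicted neoepitopes")
print(panel.loci.head(5).to_string(index=False))
# Coverage is the fraction of this patient's predicted neoepitopes whose
# coding mutation the panel will track in plasma.
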