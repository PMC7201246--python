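# icptrack

Personalized neoantigen-panel ctDNA tracking for checkpoint-blockade
monitoring.

Somatic mutation spectra in solid tumors are so heterogeneous between
patients that fixed commercial ctDNA gene panels cover only a sliver of any
one patient's mutations. `icptrack` implements the alternative: design an
**individually customized panel (ICP)** per patient from their predicted
neoantigens, sequence it serially in plasma, and read treatment response off
the ctDNA kinetics. The package is aimed at computational oncologists who
want the full analysis chain — variant retention, clonality, panel design,
heterogeneity statistics, kinetics and survival — as a tested, scriptable
library, plus a synthetic cohort generator so every stage can be exercised
without patient data.

## What it computes

- **Variant retention** — drop variants in genomicSuperDups with VAF < 0.2
  or with PopFreqMax > 0.05; retain nonsynonymous SNVs with VAF > 3%
  (> 1% at cancer hotspots). TMB = nonsynonymous SNVs per Mb of coding
  sequence.
- **Clonality** — CCF = VAF · (p·C_t + (1−p)·C_n) / (p·m) for purity p,
  tumor/normal copy numbers C_t/C_n and multiplicity m (diploid defaults
  give CCF = 2·VAF). The exact Clopper–Pearson 95% CI of the VAF maps
  through the same transform; a mutation is *subclonal* when the upper CCF
  bound is < 1.
- **Panel design** — epitopes with predicted IC50 < 500 nM are binders;
  the panel takes the top min(n, 30) binder variants by affinity, or pads
  all n < 20 binders with the highest-VAF mutations to 20 loci.
- **Heterogeneity** — pairwise overlap 100·|A∩B|/|A∪B| of mutated-gene
  sets, gene recurrence counts, and panel comparisons via Kruskal–Wallis
  with Dunn's post-hoc z tests under Benjamini–Hochberg adjustment.
- **ctDNA kinetics** — detection rates over panel loci, mean MAF with
  zero-imputed undetected loci, the week-8 fold-change rule (responder ⇔
  ≥ 50% decline), time to a 50% decline by linear interpolation, Pearson
  concordance between mean MAF and SPD tumor burden, paired t tests on
  time-to-decline.
- **Outcomes** — Kaplan–Meier + log-rank split by ctDNA class, univariate
  Cox HR with monotone-likelihood flagging, Fisher exact test for responder
  over-representation among the steepest ctDNA declines.
- **Simulation** — a synthetic cohort generator (Zipf-like gene
  popularity, Beta VAFs, log-uniform IC50s, five trajectory scenarios with
  binomial read noise) that reproduces the statistical structure the
  analysis assumes.

## Worked example

```python
from icptrack import (SimParams, simulate_mutation_spectra, simulate_neoepitopes,
                      filter_variants, filter_binders, design_panel, coverage_fraction)

params = SimParams(seed=1)
variants = filter_variants(simulate_mutation_spectra(params)["P01"])
candidates = simulate_neoepitopes(variants, params)
binders = filter_binders(candidates, threshold_nm=500.0)
panel = design_panel(binders, variants, patient_id="P01")
print(len(binders), len(panel), coverage_fraction(panel, candidates))
```

prints `39 30 0.465...`: of 86 predicted epitope candidates, 39 clear the
500 nM binder threshold, the panel takes the strongest 30 variants, and it
covers 46.5% of the patient's predicted neoepitope repertoire. Running the
cohort-level script `examples/04_cohort_heterogeneity.py` on the same seed
prints

```
pairwise overlap: median 1.64% (IQR 0.77-2.26%)
gene union 1995; shared by >=2 patients: 235 (11.78%), by >3: 7 (0.35%)
Kruskal-Wallis H=19.87, p=4.85e-05
```

— the median two-patient gene overlap sits below 2%, and the per-patient
ICP covers significantly more of each patient's mutations than fixed
70-gene panels (the Kruskal–Wallis test with Dunn/BH pairwise follow-up).
Each script in `examples/` demonstrates one capability end to end; the
`icptrack` console command exposes the same stages as thin subcommands
(`simulate`, `filter`, `panel`, `overlap`, `kinetics`, `run-all`,
`fixtures`).

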