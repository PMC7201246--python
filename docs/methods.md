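# Methods

This note records the models, parameter choices and numerical conventions
behind `icptrack`, and what the synthetic cohort does and does not emulate.

## Variant retention and TMB

The retention rule is applied to annotated somatic variant tables
(annotation is an input, not something the package computes):

1. exclude variants flagged `in_superdup` with VAF < 0.2 (mapping
   artifacts in segmental duplications), and variants with
   `popfreq_max` > 0.05 (likely germline polymorphisms);
2. of the remainder, retain nonsynonymous SNVs and indels with VAF > 0.03,
   relaxed to VAF > 0.01 at annotated cancer hotspots.

All three thresholds are keyword arguments. Indels pass the same VAF gates
but are excluded from TMB, which counts nonsynonymous SNVs only, divided by
the coding footprint in Mb (default 38 Mb, the usual WES exome size).
Malformed rows (alt > total reads, inconsistent VAF, pos < 1) abort in
strict mode and are dropped with a logged row index otherwise. The filter
is idempotent and order-preserving by construction.

## Clonality

CCF = VAF · (p·C_t + (1−p)·C_n)/(p·m) with purity p, tumor/normal copy
number C_t/C_n and multiplicity m. Defaults p = 1, C_t = C_n = 2, m = 1
give CCF = 2·VAF — the simplest purity/copy-number-corrected form; all four
parameters are overridable per call. The 95% CI of the VAF is the exact
(Clopper–Pearson) binomial interval computed from beta quantiles,
`Beta(α/2; k, n−k+1)` to `Beta(1−α/2; k+1, n−k)`, pushed through the same
affine map. A mutation is *subclonal* iff the upper CCF bound is < 1.

Two deliberate choices: CCF point estimates are **not** capped at 1
(capping would mask purity misspecification), and the label rule alone uses
the boundary. A consequence worth knowing: for a mutation at true CCF
exactly 1, the truth sits on the label boundary, so the subclonal mislabel
probability equals the one-sided CI error — about 2.2–2.5% at depths
500–5000 for any equal-tailed 95% interval. Calibration is therefore stated
as CI coverage (93–97% empirically) plus near-perfect label recovery away
from the boundary (CCF ≤ 0.3 → subclonal ≥ 99% at depth 500).

## Panel design

Epitope candidates below the binder threshold (default 500 nM IC50;
`rank_score` defaults to IC50, lower = stronger, and an alternative
percentile-rank column is accepted) collapse to their coding variant,
keeping the best score per variant. With n binder variants the panel is
the top min(n, 30) by score when n ≥ 20; otherwise all n binders padded
with the highest-VAF non-panel mutations to 20 loci. "Top 20–30" is read
as a 30-cap with padding only below 20 — there is no trimming from 30 down
to 20. Ties break by higher VAF, then (chrom, pos, ref, alt)
lexicographically, making panels fully deterministic. Panels are emitted
as a TSV manifest plus BED intervals (0-based half-open, configurable
flank) around each locus.

## Heterogeneity statistics

Pairwise overlap is the Jaccard index in percent. Recurrence counts genes
mutated in ≥ 2 and in > 3 (i.e. ≥ 4) patients — the "more than three"
threshold is taken literally and is configurable. Report percentages round
half-up to two decimals. Panel comparisons use scipy's Kruskal–Wallis
omnibus test; Dunn's post-hoc z statistics are computed on pooled ranks
with the tie correction Σ(t³−t)/(12(N−1)) (count data tie heavily), and
pairwise p-values are Benjamini–Hochberg adjusted via statsmodels. The
all-identical-data corner returns H = 0, p = 1 instead of erroring.

## ctDNA kinetics

A locus is *detected* when alt reads ≥ 3 (no limit of detection is imposed
by the assay model; the threshold is a config knob). Mean MAF averages
over **all** panel loci with undetected loci contributing zero — the
declared convention; a detected-only mode exists. The week-w fold-change
divides the mean MAF of the draw nearest day 7·w (± 14-day window, ties to
the earlier draw) by baseline; zero-baseline patients are flagged and
excluded from cohort summaries rather than given infinite values. The
response rule is inclusive: fold-change ≤ 0.5 ⇔ responder. Time to a 50%
decline interpolates linearly between consecutive draws and returns "not
reached" for non-crossing series. ctDNA/burden concordance pairs each scan
with the nearest draw within the window and reports Pearson R (Spearman
optional) at two levels: per-locus pooled points and per-day mean MAF;
fewer than 3 pairs or zero variance yield NaN. Paired time comparisons use
the two-tailed paired t test with explicit degenerate paths (all-zero
differences → t = 0, p = 1; constant nonzero differences → ±∞ with a flag).

## Outcomes

Kaplan–Meier curves and the log-rank test come from lifelines; an
all-censored group reports an undefined (infinite) median. The Cox model
is univariate with Efron ties. Complete separation (all events in one
arm) raises a monotone-likelihood flag and the CI is reported unbounded —
with ~10-patient cohorts this failure mode should surface, not hide.
Responder over-representation among the steepest ctDNA declines is a
two-sided Fisher exact test on the top versus bottom half of the
fold-change ordering (stable sort; missing fold-changes placed last and
flagged).

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes, not
sequence-level data (no reads, no HLA alleles, no copy-number segments).

**Mutation spectra.** Gene identities are drawn without replacement from a
12000-gene pool with Zipf-like popularity weights r^(−α), α = 0.5 by
default. This value was fixed once by scanning α so a 10-patient cohort
shows a median pairwise gene overlap of ~1–2%, a gene union near 2000, and
a small head of genes (the pool's top ranks carry real symbols — TP53,
TTN, MUC16 — purely for readable fixtures) recurring in more than half the
cohort. Per-patient mutation counts are uniform on 38–496. True VAFs are
Beta(2, 6); read support is binomial at Poisson(500)× tissue depth;
hotspot, population-frequency and segmental-duplication flags are sprinkled
at realistic rates (5%/4%/3%). `popularity_alpha = inf` is the supported
degenerate limit in which every patient mutates the pool head
deterministically.

**Neoepitopes.** Each nonsynonymous variant yields Poisson(0.3)
peptide–HLA candidates with IC50 log-uniform on [10^1, 10^4.7] nM, putting
~46% of candidates under the 500 nM binder threshold; the closed-form pass
probability is exposed for test oracles.

**Trajectories.** Five scenarios define a tumor-burden multiplier b(t) and
a plasma multiplier c(t) (coupled loci follow c; uncoupled loci hold
baseline): *responder* decays to 0.3× by day 84 (0.45× at day 56, i.e.
halved by week 8) with a 0.25 floor; *nonresponder* drifts at 1 + 0.001·t;
*progressor* doubles every 56 days, saturating at 8× so plasma MAF stays
in range on long follow-up; *resistant_clone* pairs progressor burden with
c(t) = max(0, 1 − t/84) — every tracked neoantigen vanishes from plasma
while the tumor grows; *occult_relapse* follows the responder burden but
re-rises from day 239 to 14× baseline at day 351, the pattern of an
unmeasurable relapsing lesion. Plasma baseline MAF is tissue VAF × 0.25
(a dilution factor), observation is binomial at 2000× depth (noise can be
switched off to obtain the exact infinite-depth values), and SPD scans run
every 42 days. Blood draws default to days 0, 28, 56, 84, then every 42 —
the cadence is configurable since real schedules vary. PFS is exponential
with scenario medians (responder 420 d, occult 260 d, nonresponder 160 d,
progressor 75 d, resistant clone 65 d), censored administratively at day
540; best response maps scenario → CR/PR/SD/PD deterministically.

**What passing tests do not show.** The noise model is plain binomial read
sampling — no UMI error suppression, background error rates, or
fragment-level biology; detection rates at low MAF are therefore
optimistic. Scenario-coupled MAF is exactly proportional to burden, so
concordance checks validate the analysis arithmetic, not biological
variability. PFS is independent of the simulated kinetics except through
the scenario label.

## Problem sizes and numerics

Default test and acceptance runs use 10–20 patient cohorts, 200 simulated
trajectory patients at 10^4 plasma depth, 10^4-row filter oracles, 1000
random panel instances, 3×1000 CI calibration draws and 30×1000-patient
Cox replicates — sizes chosen so the full suite runs in well under a
minute apiece while keeping Monte-Carlo error far from every asserted
margin. All randomness flows from `numpy.random.SeedSequence` spawns of a
single seed; pipeline manifests serialize with sorted keys and no
timestamps, so a fixed seed reproduces byte-identical output.
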