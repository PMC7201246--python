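"""Synthetic cohort generator for personalized ctDNA-panel studies.

Emulates the statistical structure of a small checkpoint-blockade NSCLC
cohort profiled by WES and followed with individually customized ctDNA
panels:

* **mutation spectra** — per-patient somatic variant tables whose gene
  identities are drawn from a shared Zipf-like "popularity" distribution
  over a large gene pool, so a handful of genes (TP53-like) recur across
  patients while the vast majority are private; pairwise gene-set overlap
  between patients is on the order of 1-2%;
* **neoepitope candidates** — peptide/HLA pairs per nonsynonymous variant
  with log-uniform predicted IC50 affinities, a controllable fraction of
  which clears the 500 nM binder threshold;
* **serial ctDNA and tumor burden** — per-locus plasma MAF trajectories
  coupled to a scenario-specific tumor-burden multiplier, observed through
  binomial read sampling at a fixed depth; SPD scans on a 42-day radiology
  cadence; progression-free survival drawn per scenario with administrative
  censoring.

Five trajectory scenarios cover the clinically distinct behaviours:
``responder`` (burden halves by week 8), ``nonresponder`` (stable),
``progressor`` (exponential growth), ``resistant_clone`` (burden grows
while every panel locus vanishes from plasma — outgrowth of a clone that
lost the tracked neoantigens), and ``occult_relapse`` (radiology stays
quiet while ctDNA re-rises late, as with unmeasurable bone lesions).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import filtering, panel as panel_mod
from .panel import PanelDesign, design_panel, filter_binders

# readable fixture names for the most "popular" pool ranks; the remainder of
# the pool uses synthetic GENE_NNNNN symbols
TOP_GENE_SYMBOLS = [
    "TP53", "TTN", "MUC16", "KRAS", "EGFR", "LRP1B", "CSMD3", "RYR2",
    "USH2A", "ZFHX4", "KEAP1", "STK11", "NF1", "FAT3", "XIRP2", "SPTA1",
    "COL11A1", "PCDH15", "PCLO", "PAPPA2", "ANK2", "APOB", "CDH10",
    "DNAH9", "ERBB4", "FLG", "GPR98", "HYDIN", "NAV3", "PTPRD",
]

SCENARIO_NAMES = ("responder", "nonresponder", "progressor", "resistant_clone", "occult_relapse")

DEFAULT_SCENARIO_MIX = {
    "responder": 0.3,
    "nonresponder": 0.2,
    "progressor": 0.2,
    "resistant_clone": 0.15,
    "occult_relapse": 0.15,
}

#: default ctDNA draw schedule: monthly-ish early draws, then the 42-day
#: radiology cadence out to about a year
DEFAULT_SAMPLE_DAYS = (0, 28, 56, 84, 126, 168, 210, 252, 294, 336, 378)

RADIOLOGY_INTERVAL_DAYS = 42

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_HLA_ALLELES = ("HLA-A*02:01", "HLA-A*11:01", "HLA-B*07:02", "HLA-B*40:01", "HLA-C*07:02")
_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

PFS_CENSOR_DAYS = 540

#: median simulated PFS (days) per scenario; exponential draws
SCENARIO_PFS_MEDIAN = {
    "responder": 420.0,
    "nonresponder": 160.0,
    "progressor": 75.0,
    "resistant_clone": 65.0,
    "occult_relapse": 260.0,
}

SCENARIO_BEST_RESPONSE = {
    "responder": "PR",
    "nonresponder": "SD",
    "progressor": "PD",
    "resistant_clone": "PD",
    "occult_relapse": "PR",
}


@dataclass(frozen=True)
class SimParams:
    """Cohort-level simulation parameters.

    Defaults describe a 10-patient advanced-NSCLC cohort: 38-496 mutated
    genes per patient from a 12000-gene pool with a mildly concentrated
    popularity law, tissue WES at ~500x, plasma panel sequencing at ~2000x,
    and predicted IC50s log-uniform between 10 nM and ~50 uM.
    """

    n_patients: int = 10
    gene_pool_size: int = 12000
    popularity_alpha: float = 0.5
    mutations_per_patient_range: tuple[int, int] = (38, 496)
    hotspot_fraction: float = 0.05
    vaf_beta_params: tuple[float, float] = (2.0, 6.0)
    ic50_log10_range: tuple[float, float] = (1.0, 4.7)
    depth_tissue: int = 500
    depth_ctdna: int = 2000
    epitopes_per_variant: float = 0.3
    ctdna_dilution: float = 0.25
    scenario_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SCENARIO_MIX))
    seed: int = 0

    def __post_init__(self):
        low, high = self.mutations_per_patient_range
        if not (0 < low <= high):
            raise ValueError("mutations_per_patient_range must satisfy 0 < low <= high")
        if self.gene_pool_size < high:
            raise ValueError("gene_pool_size must be >= max mutations per patient")
        if not 0 <= self.hotspot_fraction <= 1:
            raise ValueError("hotspot_fraction must be in [0, 1]")
        if abs(sum(self.scenario_mix.values()) - 1.0) > 1e-9:
            raise ValueError("scenario_mix must sum to 1")
        for name in self.scenario_mix:
            if name not in SCENARIO_NAMES:
                raise ValueError(f"unknown scenario {name!r}")
        if not all(p >= 0 for p in self.scenario_mix.values()):
            raise ValueError("scenario_mix proportions must be nonnegative")


def gene_pool(params: SimParams) -> tuple[list[str], np.ndarray | None]:
    """Named gene pool plus normalized Zipf-like popularity weights
    (weight of rank r proportional to r**-alpha).

    ``popularity_alpha = inf`` is the degenerate limit: all popularity mass
    sits at the head of the pool, so every patient deterministically mutates
    the top-ranked genes (returned weights are None; callers take the head).
    """
    names = list(TOP_GENE_SYMBOLS[: params.gene_pool_size])
    names += [f"GENE_{i:05d}" for i in range(len(names) + 1, params.gene_pool_size + 1)]
    if math.isinf(params.popularity_alpha):
        return names, None
    ranks = np.arange(1, params.gene_pool_size + 1, dtype=float)
    with np.errstate(over="ignore"):
        w = ranks ** (-params.popularity_alpha)
    w = w / w.sum()
    return names, w


def _patient_ids(n: int) -> list[str]:
    return [f"P{i:02d}" for i in range(1, n + 1)]


def _random_snv_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n)
    shift = rng.integers(1, 4, size=n)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    return ref, alt


def simulate_patient_variants(params: SimParams, rng: np.random.Generator, patient_id: str) -> pd.DataFrame:
    """One patient's somatic variant table (one variant per mutated gene)."""
    names, weights = gene_pool(params)
    low, high = params.mutations_per_patient_range
    n = int(rng.integers(low, high + 1))
    if weights is None:  # degenerate popularity: deterministic top-n genes
        genes = np.arange(n)
    else:
        genes = rng.choice(len(names), size=n, replace=False, p=weights)
    effect = rng.choice(
        ["nonsynonymous_snv", "synonymous_snv", "indel", "other"],
        size=n,
        p=[0.85, 0.07, 0.06, 0.02],
    )
    a, b = params.vaf_beta_params
    true_vaf = rng.beta(a, b, size=n)
    total = rng.poisson(params.depth_tissue, size=n).clip(min=1)
    alt_reads = rng.binomial(total, true_vaf)
    ref, alt = _random_snv_alleles(rng, n)
    is_indel = effect == "indel"
    alt = np.where(is_indel, np.char.add(ref.astype("U8"), alt), alt)
    popfreq = np.where(rng.random(n) < 0.04, rng.uniform(0.0, 0.3, size=n), 0.0)
    df = pd.DataFrame(
        {
            "patient_id": patient_id,
            "chrom": rng.choice(_CHROMS, size=n),
            "pos": rng.integers(100_000, 200_000_000, size=n),
            "ref": ref,
            "alt": alt,
            "gene": [names[g] for g in genes],
            "effect": effect,
            "alt_reads": alt_reads,
            "total_reads": total,
            "vaf": alt_reads / total,
            "popfreq_max": popfreq,
            "is_hotspot": rng.random(n) < params.hotspot_fraction,
            "in_superdup": rng.random(n) < 0.03,
        }
    )
    return df


def simulate_mutation_spectra(params: SimParams) -> dict[str, pd.DataFrame]:
    """Per-patient somatic variant tables for the whole cohort.

    Gene identities share one popularity distribution across patients, so a
    few genes recur cohort-wide while most are private; per-patient counts
    are uniform on ``mutations_per_patient_range``. Deterministic for a
    fixed ``params.seed``.
    """
    seeds = np.random.SeedSequence([params.seed, 1]).spawn(params.n_patients)
    out = {}
    for pid, ss in zip(_patient_ids(params.n_patients), seeds):
        out[pid] = simulate_patient_variants(params, np.random.default_rng(ss), pid)
    return out


def binder_pass_fraction(params: SimParams, threshold_nm: float = 500.0) -> float:
    """Closed-form probability that a log-uniform IC50 clears the binder
    threshold (mass of the log10 interval below log10(threshold))."""
    lo, hi = params.ic50_log10_range
    return float(np.clip((math.log10(threshold_nm) - lo) / (hi - lo), 0.0, 1.0))


def simulate_neoepitopes(
    variants: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Neoepitope candidate table for one patient's variants.

    Each nonsynonymous SNV yields a Poisson(``epitopes_per_variant``) number
    of peptide/HLA candidates with IC50 drawn log-uniform on
    ``ic50_log10_range``; ``rank_score`` is the IC50 itself (lower =
    stronger binder).
    """
    if variants.empty:
        raise ValueError("empty variant table")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    nonsyn = variants.loc[variants["effect"] == "nonsynonymous_snv"]
    counts = rng.poisson(params.epitopes_per_variant, size=len(nonsyn))
    rows = nonsyn.loc[nonsyn.index.repeat(counts)]
    m = len(rows)
    lo, hi = params.ic50_log10_range
    ic50 = 10 ** rng.uniform(lo, hi, size=m)
    peptides = ["".join(p) for p in rng.choice(_AMINO_ACIDS, size=(m, 9))]
    out = pd.DataFrame(
        {
            "patient_id": rows["patient_id"].to_numpy(),
            "chrom": rows["chrom"].to_numpy(),
            "pos": rows["pos"].to_numpy(),
            "ref": rows["ref"].to_numpy(),
            "alt": rows["alt"].to_numpy(),
            "gene": rows["gene"].to_numpy(),
            "peptide": peptides,
            "hla_allele": rng.choice(_HLA_ALLELES, size=m),
            "ic50_nm": ic50,
            "rank_score": ic50,
        }
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# trajectory scenarios


def _responder_burden(t: float) -> float:
    # exponential shrinkage reaching 30% of baseline at day 84, then plateau
    return max(0.25, math.exp(-math.log(1 / 0.3) / 84.0 * t))


def _nonresponder_burden(t: float) -> float:
    return 1.0 + 0.001 * t


def _progressor_burden(t: float) -> float:
    # doubling every 8 weeks, plateauing at 8x baseline (growth saturates
    # and keeps plasma MAF inside its physical range on long follow-up)
    return min(8.0, math.exp(math.log(2.0) / 56.0 * t))


def _resistant_ctdna(t: float) -> float:
    # tracked neoantigens vanish from plasma while the tumor grows
    return max(0.0, 1.0 - t / 84.0)


def _occult_burden(t: float) -> float:
    return max(0.2, math.exp(-math.log(1 / 0.3) / 84.0 * t))


def _occult_ctdna(t: float) -> float:
    # follows the radiological response, then re-rises from day 239 to a
    # 14-fold elevation at day 351 (occult, unmeasurable relapse)
    if t < 239:
        return _occult_burden(t)
    base = _occult_burden(239.0)
    return base + (14.0 - base) * (t - 239.0) / (351.0 - 239.0)


@dataclass(frozen=True)
class TrajectoryScenario:
    """One clinical trajectory: a tumor-burden multiplier over time, the
    plasma multiplier coupled loci follow (defaults to the burden), the
    coupled fraction of panel loci, and the ctDNA draw schedule."""

    name: str
    burden_fn: Callable[[float], float]
    ctdna_fn: Callable[[float], float] | None = None
    ctdna_coupling: float = 1.0
    sample_days: tuple[int, ...] = DEFAULT_SAMPLE_DAYS

    def __post_init__(self):
        days = list(self.sample_days)
        if days != sorted(days) or days[0] != 0:
            raise ValueError("sample_days must be sorted ascending and start at 0 (baseline)")
        if any(d < 0 for d in days):
            raise ValueError("negative sample days")
        if not 0 <= self.ctdna_coupling <= 1:
            raise ValueError("ctdna_coupling must be in [0, 1]")
        if any(self.burden_fn(d) <= 0 for d in days):
            raise ValueError("burden multiplier must be positive at all sampled days")
        if self.name == "responder" and self.burden_fn(56) > 0.5:
            raise ValueError("responder must reach <= 0.5x baseline burden by day 56")

    def ctdna_multiplier(self, t: float) -> float:
        return (self.ctdna_fn or self.burden_fn)(t)


_SCENARIO_FNS: dict[str, tuple[Callable, Callable | None]] = {
    "responder": (_responder_burden, None),
    "nonresponder": (_nonresponder_burden, None),
    "progressor": (_progressor_burden, None),
    "resistant_clone": (_progressor_burden, _resistant_ctdna),
    "occult_relapse": (_occult_burden, _occult_ctdna),
}


def make_scenario(
    name: str,
    ctdna_coupling: float = 1.0,
    sample_days: Sequence[int] = DEFAULT_SAMPLE_DAYS,
) -> TrajectoryScenario:
    """Canonical scenario by name (see module docstring)."""
    if name not in _SCENARIO_FNS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    burden_fn, ctdna_fn = _SCENARIO_FNS[name]
    return TrajectoryScenario(
        name=name,
        burden_fn=burden_fn,
        ctdna_fn=ctdna_fn,
        ctdna_coupling=ctdna_coupling,
        sample_days=tuple(sample_days),
    )


def simulate_serial_ctdna(
    panel: PanelDesign,
    scenario: TrajectoryScenario,
    params: SimParams,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    baseline_spd_mm2: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Serial plasma MAF per panel locus, SPD scans and the outcome record.

    The true MAF of a coupled locus at day t is its baseline plasma MAF
    (tissue VAF x ``ctdna_dilution``) times the scenario's plasma
    multiplier; uncoupled loci hold their baseline. Observation is binomial
    read sampling at ``depth_ctdna``; ``noise=False`` returns the exact
    expected MAF (the infinite-depth limit, with fractional alt_reads).
    SPD scans run on the 42-day radiology cadence; PFS is exponential with
    a scenario-specific median, censored administratively at day 540.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    keys = panel.keys
    base_maf = (panel.loci["vaf"].to_numpy(dtype=float) * params.ctdna_dilution).clip(0.0, 0.999)
    n_loci = len(keys)
    n_coupled = int(round(scenario.ctdna_coupling * n_loci))
    coupled = np.zeros(n_loci, dtype=bool)
    if n_coupled:
        coupled[rng.choice(n_loci, size=n_coupled, replace=False)] = True
    rows = []
    for day in scenario.sample_days:
        mult = scenario.ctdna_multiplier(float(day))
        true = np.where(coupled, base_maf * mult, base_maf).clip(0.0, 0.999)
        if noise:
            alt = rng.binomial(params.depth_ctdna, true).astype(float)
        else:
            alt = true * params.depth_ctdna
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": panel.patient_id,
                    "locus": keys,
                    "day": int(day),
                    "alt_reads": alt,
                    "depth": params.depth_ctdna,
                    "maf": alt / params.depth_ctdna,
                }
            )
        )
    ctdna = pd.concat(rows, ignore_index=True)

    if baseline_spd_mm2 is None:
        baseline_spd_mm2 = float(rng.uniform(1000.0, 6000.0))
    scan_days = range(0, max(scenario.sample_days) + 1, RADIOLOGY_INTERVAL_DAYS)
    burden = pd.DataFrame(
        {
            "patient_id": panel.patient_id,
            "day": list(scan_days),
            "spd_mm2": [baseline_spd_mm2 * scenario.burden_fn(float(d)) for d in scan_days],
        }
    )

    scale = SCENARIO_PFS_MEDIAN[scenario.name] / math.log(2.0)
    pfs = rng.exponential(scale)
    event = pfs <= PFS_CENSOR_DAYS
    outcome = {
        "patient_id": panel.patient_id,
        "scenario": scenario.name,
        "pfs_days": int(round(min(pfs, PFS_CENSOR_DAYS))),
        "event": bool(event),
        "best_response": SCENARIO_BEST_RESPONSE[scenario.name],
    }
    return ctdna, burden, outcome


# ---------------------------------------------------------------------------
# full-cohort orchestration


def allocate_scenarios(params: SimParams, rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder apportionment of scenario_mix over
    the cohort, then a seeded shuffle of the assignment order."""
    names = [n for n in SCENARIO_NAMES if n in params.scenario_mix]
    quotas = {n: params.scenario_mix[n] * params.n_patients for n in names}
    counts = {n: int(math.floor(q)) for n, q in quotas.items()}
    leftover = params.n_patients - sum(counts.values())
    by_remainder = sorted(names, key=lambda n: (-(quotas[n] - counts[n]), n))
    for n in by_remainder[:leftover]:
        counts[n] += 1
    alloc = [n for n in names for _ in range(counts[n])]
    return [alloc[i] for i in rng.permutation(len(alloc))]


@dataclass
class Cohort:
    """A fully simulated cohort: every table the analysis pipeline consumes."""

    params: SimParams
    variants: dict[str, pd.DataFrame]  # raw spectra per patient
    retained: dict[str, pd.DataFrame]  # post-filter spectra
    neoepitopes: dict[str, pd.DataFrame]
    panels: dict[str, PanelDesign]
    scenarios: dict[str, str]
    ctdna: pd.DataFrame  # long format, all patients
    burden: pd.DataFrame
    outcomes: pd.DataFrame

    @property
    def patient_ids(self) -> list[str]:
        return list(self.variants)

    def spectra(self, retained: bool = True) -> dict[str, set]:
        src = self.retained if retained else self.variants
        return {pid: set(df["gene"]) for pid, df in src.items()}


def simulate_cohort(params: SimParams, binder_threshold_nm: float = 500.0) -> Cohort:
    """End-to-end cohort simulation: spectra -> filter -> neoepitopes ->
    panel design -> serial ctDNA/burden/outcomes per scenario."""
    variants = simulate_mutation_spectra(params)
    master = np.random.SeedSequence([params.seed, 4]).spawn(3)
    rng_scen = np.random.default_rng(master[0])
    epi_seeds = np.random.SeedSequence([params.seed, 5]).spawn(params.n_patients)
    traj_seeds = np.random.SeedSequence([params.seed, 6]).spawn(params.n_patients)
    scenario_names = allocate_scenarios(params, rng_scen)

    retained, neo, panels, scen = {}, {}, {}, {}
    ctdna_parts, burden_parts, outcome_rows = [], [], []
    for i, pid in enumerate(variants):
        retained[pid] = filtering.filter_variants(variants[pid])
        neo[pid] = simulate_neoepitopes(retained[pid], params, np.random.default_rng(epi_seeds[i]))
        binders = filter_binders(neo[pid], binder_threshold_nm) if len(neo[pid]) else neo[pid]
        p = design_panel(binders, retained[pid], patient_id=pid)
        if len(neo[pid]):
            p.coverage_fraction = panel_mod.coverage_fraction(p, neo[pid])
        panels[pid] = p
        scen[pid] = scenario_names[i]
        scenario = make_scenario(scenario_names[i])
        c, b, o = simulate_serial_ctdna(p, scenario, params, np.random.default_rng(traj_seeds[i]))
        ctdna_parts.append(c)
        burden_parts.append(b)
        outcome_rows.append(o)
    return Cohort(
        params=params,
        variants=variants,
        retained=retained,
        neoepitopes=neo,
        panels=panels,
        scenarios=scen,
        ctdna=pd.concat(ctdna_parts, ignore_index=True),
        burden=pd.concat(burden_parts, ignore_index=True),
        outcomes=pd.DataFrame(outcome_rows),
    )
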