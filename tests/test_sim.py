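"""Synthetic cohort generator: determinism, popularity structure, coupling."""

import math

import numpy as np
import pandas as pd
import pytest

from icptrack.kinetics import mean_maf, sample_days
from icptrack.overlap import cohort_overlap_summary
from icptrack.panel import PanelDesign
from icptrack.sim import (
    SimParams,
    binder_pass_fraction,
    make_scenario,
    simulate_cohort,
    simulate_mutation_spectra,
    simulate_neoepitopes,
    simulate_serial_ctdna,
)


def spectra_of(tables):
    return {pid: set(df["gene"]) for pid, df in tables.items()}


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimParams(gene_pool_size=50, mutations_per_patient_range=(10, 100))
    with pytest.raises(ValueError):
        SimParams(mutations_per_patient_range=(100, 10))
    with pytest.raises(ValueError):
        SimParams(scenario_mix={"responder": 0.5})
    with pytest.raises(ValueError):
        SimParams(scenario_mix={"responder": 0.5, "bogus": 0.5})


def test_seed_determinism_byte_identical():
    p = SimParams(n_patients=4, mutations_per_patient_range=(20, 60), seed=42)
    a = simulate_mutation_spectra(p)
    b = simulate_mutation_spectra(p)
    assert list(a) == list(b)
    for pid in a:
        assert a[pid].to_csv() == b[pid].to_csv()
    c1, c2 = simulate_cohort(p), simulate_cohort(p)
    assert c1.ctdna.to_csv() == c2.ctdna.to_csv()
    assert c1.outcomes.to_csv() == c2.outcomes.to_csv()


def test_mutation_counts_within_range_and_pool_respected():
    p = SimParams(n_patients=5, mutations_per_patient_range=(30, 50), seed=2)
    tables = simulate_mutation_spectra(p)
    for df in tables.values():
        assert 30 <= len(df) <= 50
        assert df["gene"].nunique() == len(df)  # drawn without replacement
        assert (df["alt_reads"] <= df["total_reads"]).all()
        assert (df["pos"] >= 1).all()


def test_degenerate_popularity_gives_full_overlap():
    """In the degenerate popularity limit with equal mutation counts, every
    patient mutates the same genes."""
    p = SimParams(
        n_patients=3,
        gene_pool_size=1000,
        popularity_alpha=math.inf,
        mutations_per_patient_range=(30, 30),
        seed=3,
    )
    s = cohort_overlap_summary(spectra_of(simulate_mutation_spectra(p)))
    assert s.median == 100.0


def test_uniform_popularity_matches_hypergeometric_expectation():
    """alpha = 0 (uniform pool): mean pairwise intersection ~ m^2 / N, so the
    Jaccard overlap concentrates near m^2/N / (2m - m^2/N)."""
    m, pool = 60, 800
    p = SimParams(
        n_patients=12,
        gene_pool_size=pool,
        popularity_alpha=0.0,
        mutations_per_patient_range=(m, m),
        seed=4,
    )
    s = cohort_overlap_summary(spectra_of(simulate_mutation_spectra(p)))
    exp_inter = m * m / pool
    exp_overlap = 100 * exp_inter / (2 * m - exp_inter)
    assert abs(np.mean(s.pairwise_values) - exp_overlap) < 1.5


def test_popularity_alpha_monotone_in_overlap():
    """Median pairwise overlap increases with the popularity exponent
    (averaged over seeds)."""
    def med(alpha):
        vals = []
        for seed in range(20):
            p = SimParams(
                n_patients=5,
                gene_pool_size=2000,
                popularity_alpha=alpha,
                mutations_per_patient_range=(60, 60),
                seed=seed,
            )
            vals.append(cohort_overlap_summary(spectra_of(simulate_mutation_spectra(p))).median)
        return np.mean(vals)

    m0, m1, m2 = med(0.2), med(0.8), med(1.4)
    assert m0 < m1 < m2


def test_default_cohort_overlap_in_low_percent_range():
    """Default parameters emulate strong inter-patient heterogeneity: median
    pairwise overlap of a 10-patient cohort sits in the low percent range."""
    vals = [
        cohort_overlap_summary(spectra_of(simulate_mutation_spectra(SimParams(seed=s)))).median
        for s in range(3)
    ]
    assert 0.5 <= np.median(vals) <= 4.0


def test_neoepitope_threshold_extremes_and_pass_fraction():
    p = SimParams(n_patients=2, mutations_per_patient_range=(60, 80), seed=5)
    variants = simulate_mutation_spectra(p)["P01"]
    strong = SimParams(seed=5, ic50_log10_range=(1.0, math.log10(400)))
    neo = simulate_neoepitopes(variants, strong)
    assert (neo["ic50_nm"] < 500).all()
    weak = SimParams(seed=5, ic50_log10_range=(math.log10(600), math.log10(50000)))
    neo = simulate_neoepitopes(variants, weak)
    assert (neo["ic50_nm"] >= 500).all()
    assert binder_pass_fraction(strong) == 1.0
    assert binder_pass_fraction(weak) == 0.0


def test_neoepitope_pass_fraction_within_binomial_noise():
    """Observed binder fraction within 3 sigma of the log-uniform mass below
    500 nM (binomial oracle)."""
    p = SimParams(n_patients=1, mutations_per_patient_range=(400, 496), epitopes_per_variant=3.0, seed=6)
    variants = simulate_mutation_spectra(p)["P01"]
    neo = simulate_neoepitopes(variants, p)
    q = binder_pass_fraction(p)
    n = len(neo)
    obs = (neo["ic50_nm"] < 500).mean()
    assert abs(obs - q) <= 3 * math.sqrt(q * (1 - q) / n)
    with pytest.raises(ValueError):
        simulate_neoepitopes(variants.iloc[:0], p)


def _toy_panel(n_loci=10, vaf=0.3, pid="P01"):
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_loci + 1) * 1000,
            "ref": "A",
            "alt": "T",
            "gene": [f"G{i}" for i in range(n_loci)],
            "vaf": vaf,
            "rank_score": 100.0,
            "source": "neoantigen",
        }
    )
    return PanelDesign(patient_id=pid, loci=loci)


def test_noise_free_responder_fold_change_equals_burden_multiplier():
    p = SimParams(seed=7)
    scenario = make_scenario("responder")
    ctdna, burden, outcome = simulate_serial_ctdna(_toy_panel(), scenario, p, noise=False)
    loci = [f"chr1:{(i + 1) * 1000}:A:T" for i in range(10)]
    fc = mean_maf(ctdna, 56, loci, min_alt_reads=0) / mean_maf(ctdna, 0, loci, min_alt_reads=0)
    assert fc == pytest.approx(scenario.burden_fn(56), rel=1e-12)


def test_resistant_clone_decouples_ctdna_from_burden():
    p = SimParams(seed=8)
    ctdna, burden, _ = simulate_serial_ctdna(_toy_panel(), make_scenario("resistant_clone"), p)
    last_day = max(sample_days(ctdna))
    late = ctdna.loc[ctdna["day"] == last_day, "maf"]
    assert (late == 0).all()  # every tracked neoantigen vanished from plasma
    assert burden["spd_mm2"].iloc[-1] > burden["spd_mm2"].iloc[0]


def test_occult_relapse_ctdna_rerises_late():
    p = SimParams(seed=9)
    scenario = make_scenario("occult_relapse")
    ctdna, burden, _ = simulate_serial_ctdna(_toy_panel(vaf=0.2), scenario, p, noise=False)
    loci = [f"chr1:{(i + 1) * 1000}:A:T" for i in range(10)]
    base = mean_maf(ctdna, 0, loci, min_alt_reads=0)
    mid = mean_maf(ctdna, 84, loci, min_alt_reads=0)
    late = mean_maf(ctdna, 336, loci, min_alt_reads=0)
    assert mid < 0.5 * base  # early molecular response
    assert late > 2 * base  # late re-elevation despite quiet radiology
    assert burden["spd_mm2"].iloc[-1] < burden["spd_mm2"].iloc[0]


def test_serial_ctdna_rejects_bad_schedules():
    p = SimParams(seed=10)
    with pytest.raises(ValueError):
        make_scenario("responder", sample_days=(0, 56, 28))
    with pytest.raises(ValueError):
        make_scenario("responder", sample_days=(28, 56))
    with pytest.raises(ValueError):
        simulate_serial_ctdna(PanelDesign("P", _toy_panel().loci.iloc[:0]), make_scenario("responder"), p)


def test_coupled_ctdna_tracks_burden(cohort):
    """With full coupling and deep sequencing, per-day mean MAF correlates
    with SPD at R > 0.95 for monotone scenarios."""
    p = SimParams(seed=13, depth_ctdna=10_000)
    for name in ("responder", "progressor"):
        scenario = make_scenario(name, ctdna_coupling=1.0)
        ctdna, burden, _ = simulate_serial_ctdna(_toy_panel(), scenario, p)
        loci = [f"chr1:{(i + 1) * 1000}:A:T" for i in range(10)]
        days = [d for d in sample_days(ctdna) if d % 42 == 0]
        x = [mean_maf(ctdna, d, loci) for d in days]
        y = [burden.loc[burden["day"] == d, "spd_mm2"].iloc[0] for d in days]
        r = np.corrcoef(x, y)[0, 1]
        assert r > 0.95


def test_responder_pfs_exceeds_progressor_on_average():
    rng_pfs = []
    for seed in range(15):
        p = SimParams(seed=seed)
        sc_r, _, out_r = simulate_serial_ctdna(_toy_panel(), make_scenario("responder"), p,
                                               rng=np.random.default_rng(seed))
        _, _, out_p = simulate_serial_ctdna(_toy_panel(), make_scenario("progressor"), p,
                                            rng=np.random.default_rng(seed + 1000))
        rng_pfs.append((out_r["pfs_days"], out_p["pfs_days"]))
    med_r = np.median([a for a, _ in rng_pfs])
    med_p = np.median([b for _, b in rng_pfs])
    assert med_r > med_p


def test_cohort_bundles_all_scenarios_and_tables(cohort):
    assert set(cohort.scenarios.values()) <= {
        "responder", "nonresponder", "progressor", "resistant_clone", "occult_relapse"
    }
    assert len(cohort.outcomes) == cohort.params.n_patients
    for pid in cohort.patient_ids:
        assert len(cohort.panels[pid]) >= 20
        assert set(cohort.ctdna.loc[cohort.ctdna["patient_id"] == pid, "locus"]) == set(
            cohort.panels[pid].keys
        )
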