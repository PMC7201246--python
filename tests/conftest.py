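import numpy as np
import pandas as pd
import pytest

from icptrack import SimParams, simulate_cohort


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gene="TP53",
    effect="nonsynonymous_snv",
    alt_reads=50,
    total_reads=500,
    popfreq_max=0.0,
    is_hotspot=False,
    in_superdup=False,
    patient_id="P01",
    vaf=None,
):
    return {
        "patient_id": patient_id,
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": gene,
        "effect": effect,
        "alt_reads": alt_reads,
        "total_reads": total_reads,
        "vaf": vaf if vaf is not None else alt_reads / total_reads,
        "popfreq_max": popfreq_max,
        "is_hotspot": is_hotspot,
        "in_superdup": in_superdup,
    }


def variant_table(rows):
    return pd.DataFrame(rows)


def random_variant_table(rng, n, vaf_choices=None):
    """Random variant table hitting all flag combinations and, optionally,
    exact boundary VAFs."""
    effects = rng.choice(
        ["nonsynonymous_snv", "synonymous_snv", "indel", "other"], size=n, p=[0.6, 0.15, 0.15, 0.1]
    )
    if vaf_choices is not None:
        vaf = rng.choice(vaf_choices, size=n)
        # depths divisible by 1000 keep the boundary VAFs exactly consistent
        total = rng.choice([200, 400, 600, 800, 1000], size=n)
        alt = np.round(vaf * total).astype(int)
    else:
        total = rng.integers(50, 1000, size=n)
        alt = rng.integers(0, total + 1)
        vaf = alt / total
    return pd.DataFrame(
        {
            "patient_id": "P01",
            "chrom": rng.choice([f"chr{i}" for i in range(1, 5)], size=n),
            "pos": rng.integers(1, 10**8, size=n),
            "ref": rng.choice(list("ACGT"), size=n),
            "alt": rng.choice(list("ACGT"), size=n),
            "gene": [f"G{i}" for i in range(n)],
            "effect": effects,
            "alt_reads": alt,
            "total_reads": total,
            "vaf": vaf,
            "popfreq_max": rng.choice([0.0, 0.01, 0.05, 0.06, 0.2], size=n),
            "is_hotspot": rng.random(n) < 0.3,
            "in_superdup": rng.random(n) < 0.3,
        }
    )


@pytest.fixture(scope="session")
def small_params():
    """A compact cohort: fast but structurally complete."""
    return SimParams(n_patients=6, mutations_per_patient_range=(40, 120), seed=11)


@pytest.fixture(scope="session")
def cohort(small_params):
    return simulate_cohort(small_params)
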