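"""Somatic variant retention rules, TMB and per-mutation clonality.

Variants arrive as a pandas DataFrame with one row per mutation and the
columns listed in :data:`VARIANT_COLUMNS` (an ANNOVAR-style annotated table:
read support, population frequency, hotspot and segmental-duplication flags).
The retention rule mirrors a typical tumor-only WES pipeline:

* exclude anything inside a segmental duplication with VAF < 0.2;
* exclude anything with a maximum population frequency > 0.05;
* keep nonsynonymous SNVs (and indels) with VAF > 3%, relaxed to VAF > 1%
  at annotated cancer hotspots.

Clonality is assessed per mutation from the cancer cell fraction (CCF): the
VAF is mapped to a CCF through the tumor purity, local copy number and
mutation multiplicity, the exact (Clopper-Pearson) binomial 95% CI of the
VAF is mapped through the same affine transform, and a mutation is called
subclonal when the upper CCF bound falls below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column set for a somatic variant table
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "alt_reads",
    "total_reads",
    "vaf",
    "popfreq_max",
    "is_hotspot",
    "in_superdup",
]

EFFECTS = ("nonsynonymous_snv", "synonymous_snv", "indel", "other")

#: effects that pass the functional part of the retention rule
RETAINED_EFFECTS = ("nonsynonymous_snv", "indel")


class MalformedVariantError(ValueError):
    """A variant row violates the table invariants (strict mode only)."""


def variant_key(chrom, pos, ref, alt) -> str:
    """Canonical ``chrom:pos:ref:alt`` identifier for one mutation."""
    return f"{chrom}:{pos}:{ref}:{alt}"


def add_variant_keys(variants: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of *variants* with a ``key`` column."""
    out = variants.copy()
    out["key"] = (
        out["chrom"].astype(str)
        + ":"
        + out["pos"].astype(str)
        + ":"
        + out["ref"].astype(str)
        + ":"
        + out["alt"].astype(str)
    )
    return out


def validate_variants(variants: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Check table invariants; drop (lenient) or raise on (strict) bad rows.

    Invariants: ``0 <= alt_reads <= total_reads``, ``pos >= 1`` and ``vaf``
    consistent with the read counts to within rounding (|vaf - alt/total|
    <= 0.005).
    """
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise MalformedVariantError(f"missing variant columns: {missing}")
    v = variants
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = v["alt_reads"] / v["total_reads"]
    bad = (
        (v["alt_reads"] < 0)
        | (v["alt_reads"] > v["total_reads"])
        | (v["pos"] < 1)
        | ((v["total_reads"] > 0) & (np.abs(v["vaf"] - implied) > 0.005))
    )
    if bad.any():
        rows = list(v.index[bad])
        if strict:
            raise MalformedVariantError(f"malformed variant rows at index {rows}")
        logger.warning("dropping %d malformed variant rows: %s", len(rows), rows)
        return v.loc[~bad]
    return v


def filter_variants(
    variants: pd.DataFrame,
    *,
    vaf_min: float = 0.03,
    hotspot_vaf_min: float = 0.01,
    superdup_vaf_max: float = 0.2,
    popfreq_cutoff: float = 0.05,
    strict: bool = False,
    return_counts: bool = False,
):
    """Apply the somatic retention rules; order-preserving.

    Drops variants in segmental duplications with VAF below
    *superdup_vaf_max* and variants with population frequency above
    *popfreq_cutoff*; of the rest, retains nonsynonymous SNVs (and indels)
    with VAF strictly above *vaf_min*, or above *hotspot_vaf_min* at
    hotspots. Per-rule drop counts are logged; pass ``return_counts=True``
    to also get them as a dict.
    """
    v = validate_variants(variants, strict=strict)
    superdup_drop = v["in_superdup"].astype(bool) & (v["vaf"] < superdup_vaf_max)
    popfreq_drop = v["popfreq_max"] > popfreq_cutoff
    excluded = superdup_drop | popfreq_drop
    effect_ok = v["effect"].isin(RETAINED_EFFECTS)
    vaf_ok = (v["vaf"] > vaf_min) | (v["is_hotspot"].astype(bool) & (v["vaf"] > hotspot_vaf_min))
    keep = ~excluded & effect_ok & vaf_ok
    counts = {
        "input": int(len(v)),
        "dropped_superdup_low_vaf": int(superdup_drop.sum()),
        "dropped_popfreq": int(popfreq_drop.sum()),
        "dropped_effect": int((~excluded & ~effect_ok).sum()),
        "dropped_low_vaf": int((~excluded & effect_ok & ~vaf_ok).sum()),
        "retained": int(keep.sum()),
    }
    logger.info("variant filter: %s", counts)
    retained = v.loc[keep]
    if return_counts:
        return retained, counts
    return retained


def compute_tmb(retained: pd.DataFrame, coding_mb: float = 38.0) -> float:
    """Tumor mutational burden: nonsynonymous SNVs per megabase of coding
    sequence. Indels and other effects do not count."""
    if coding_mb <= 0:
        raise ValueError("coding_mb must be positive")
    n = int((retained["effect"] == "nonsynonymous_snv").sum())
    return n / coding_mb


def clopper_pearson(alt_reads, total_reads, alpha: float = 0.05):
    """Exact binomial CI for a proportion, from beta quantiles. Vectorized.

    Returns ``(low, high)`` arrays (or scalars) with ``low = 0`` at
    ``alt_reads = 0`` and ``high = 1`` at ``alt_reads = total_reads``.
    """
    k = np.asarray(alt_reads, dtype=float)
    n = np.asarray(total_reads, dtype=float)
    with np.errstate(invalid="ignore"):
        low = stats.beta.ppf(alpha / 2, k, n - k + 1)
        high = stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    low = np.where(k == 0, 0.0, low)
    high = np.where(k == n, 1.0, high)
    if np.isscalar(alt_reads) or np.ndim(alt_reads) == 0:
        return float(low), float(high)
    return low, high


@dataclass(frozen=True)
class ClonalityCall:
    """CCF point estimate with exact 95% CI and the clonal/subclonal label."""

    ccf: float
    ccf_low: float
    ccf_high: float
    label: str  # "clonal" | "subclonal"
    purity: float
    tumor_cn: int
    normal_cn: int
    multiplicity: int


def _ccf_factor(purity: float, tumor_cn: int, normal_cn: int, multiplicity: int) -> float:
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    return (purity * tumor_cn + (1 - purity) * normal_cn) / (purity * multiplicity)


def call_clonality(
    alt_reads: int,
    total_reads: int,
    purity: float = 1.0,
    tumor_cn: int = 2,
    normal_cn: int = 2,
    multiplicity: int = 1,
    strict: bool = False,
) -> ClonalityCall:
    """CCF with 95% CI from binomial read counts; subclonal iff the upper
    CCF bound is below 1.

    With the diploid defaults (purity 1, copy number 2/2, multiplicity 1)
    the CCF is simply twice the VAF; the point estimate is deliberately not
    capped at 1 so purity misspecification remains visible.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if alt_reads == 0 and strict:
        raise ValueError("undetected variant (alt_reads = 0): clonality undefined")
    factor = _ccf_factor(purity, tumor_cn, normal_cn, multiplicity)
    vaf = alt_reads / total_reads
    low, high = clopper_pearson(alt_reads, total_reads)
    ccf, ccf_low, ccf_high = vaf * factor, low * factor, high * factor
    label = "subclonal" if ccf_high < 1 else "clonal"
    return ClonalityCall(ccf, ccf_low, ccf_high, label, purity, tumor_cn, normal_cn, multiplicity)


def call_clonality_table(
    variants: pd.DataFrame,
    purity: float = 1.0,
    tumor_cn: int = 2,
    normal_cn: int = 2,
    multiplicity: int = 1,
) -> pd.DataFrame:
    """Vectorized :func:`call_clonality`: returns *variants* plus the columns
    ``ccf``, ``ccf_low``, ``ccf_high`` and ``clonality``."""
    factor = _ccf_factor(purity, tumor_cn, normal_cn, multiplicity)
    out = variants.copy()
    vaf = out["alt_reads"] / out["total_reads"]
    low, high = clopper_pearson(out["alt_reads"].to_numpy(), out["total_reads"].to_numpy())
    out["ccf"] = vaf * factor
    out["ccf_low"] = low * factor
    out["ccf_high"] = high * factor
    out["clonality"] = np.where(out["ccf_high"] < 1, "subclonal", "clonal")
    return out
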