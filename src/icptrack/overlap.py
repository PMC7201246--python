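"""Cohort mutation-spectrum heterogeneity and panel comparisons.

A cohort spectrum is a mapping ``patient_id -> set of mutated gene symbols``.
Pairwise overlap between two patients is the Jaccard index of their gene
sets in percent (100 x |intersection| / |union|); cohort heterogeneity is
summarized by the distribution of all pairwise overlaps and by gene
recurrence counts. Fixed gene panels (commercial liquid-biopsy panels) are
compared with per-patient customized panels by the number of patient genes
each covers, using a Kruskal-Wallis omnibus test with Dunn's tie-corrected
post-hoc z tests and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GenePanel:
    """A fixed gene panel (e.g. a commercial ctDNA assay gene list)."""

    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene panel is empty")


def read_gene_panel(path, name: str | None = None) -> GenePanel:
    """Read a panel from one-symbol-per-line text or a two-column TSV
    (symbol in the first column)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split("\t")[0])
    import os

    return GenePanel(name or os.path.basename(str(path)), frozenset(genes))


def overlap_percentage(a: set, b: set) -> float:
    """Jaccard overlap of two gene sets in percent."""
    union = set(a) | set(b)
    if not union:
        raise ValueError("overlap undefined for two empty gene sets")
    return 100.0 * len(set(a) & set(b)) / len(union)


@dataclass
class OverlapSummary:
    median: float
    q1: float
    q3: float
    matrix: pd.DataFrame  # symmetric, 100 on the diagonal

    @property
    def pairwise_values(self) -> np.ndarray:
        m = self.matrix.to_numpy()
        iu = np.triu_indices_from(m, k=1)
        return m[iu]


def cohort_overlap_summary(spectra: Mapping[str, set]) -> OverlapSummary:
    """All unordered pairwise overlaps plus median and quartiles."""
    if len(spectra) < 2:
        raise ValueError("need at least two patients")
    ids = list(spectra)
    m = pd.DataFrame(100.0, index=ids, columns=ids)
    vals = []
    for a, b in itertools.combinations(ids, 2):
        o = overlap_percentage(spectra[a], spectra[b])
        m.loc[a, b] = m.loc[b, a] = o
        vals.append(o)
    vals = np.asarray(vals)
    return OverlapSummary(
        median=float(np.median(vals)),
        q1=float(np.percentile(vals, 25)),
        q3=float(np.percentile(vals, 75)),
        matrix=m,
    )


def _round2(x: float) -> float:
    """Round half-up to two decimals (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def recurrence_percentage(count: int, union_size: int) -> float:
    """Share of the cohort gene union, in percent rounded to 2 decimals."""
    if union_size <= 0:
        raise ValueError("union_size must be positive")
    return _round2(100.0 * count / union_size)


@dataclass(frozen=True)
class RecurrenceStats:
    union_size: int
    n_shared_ge2: int  # genes mutated in >= 2 patients
    n_shared_gt3: int  # genes mutated in > 3 patients (i.e. >= 4)
    pct_ge2: float
    pct_gt3: float


def recurrence_stats(
    spectra: Mapping[str, set],
    shared_min: int = 2,
    more_than: int = 3,
) -> RecurrenceStats:
    """Gene recurrence across the cohort: union size, counts of genes shared
    by >= *shared_min* and by > *more_than* patients, and their percentages
    of the union (2 decimals, half-up)."""
    if not spectra:
        raise ValueError("empty cohort")
    counts = Counter(g for genes in spectra.values() for g in set(genes))
    union_size = len(counts)
    n_ge2 = sum(1 for c in counts.values() if c >= shared_min)
    n_gt3 = sum(1 for c in counts.values() if c > more_than)
    return RecurrenceStats(
        union_size=union_size,
        n_shared_ge2=n_ge2,
        n_shared_gt3=n_gt3,
        pct_ge2=recurrence_percentage(n_ge2, union_size),
        pct_gt3=recurrence_percentage(n_gt3, union_size),
    )


def panel_spectrum_overlap(panel: GenePanel, spectra: Mapping[str, set]) -> dict:
    """Per-patient count of mutated genes covered by a fixed panel."""
    if not spectra:
        raise ValueError("empty cohort")
    return {pid: len(panel.genes & set(genes)) for pid, genes in spectra.items()}


@dataclass
class PanelComparison:
    h: float
    p: float
    pairwise: pd.DataFrame  # columns: group1, group2, z, p, p_adj


def _dunn_pairwise(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks with tie correction."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # mean rank per group
    mean_rank, start = {}, 0
    for g in names:
        mean_rank[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(names, 2):
        se2 = var_base * (1.0 / sizes[a] + 1.0 / sizes[b])
        if se2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(se2)
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p": p})
    return pd.DataFrame(rows)


def compare_panels(count_groups: Mapping[str, Sequence[float]]) -> PanelComparison:
    """Kruskal-Wallis across panel count groups plus Dunn/BH pairwise tests.

    All-identical data (zero variance everywhere) takes the degenerate
    ``H = 0, p = 1`` path rather than erroring.
    """
    if len(count_groups) < 2:
        raise ValueError("need at least two groups")
    for g, vals in count_groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than two observations")
    arrays = [np.asarray(v, dtype=float) for v in count_groups.values()]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    pairwise = _dunn_pairwise(count_groups)
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return PanelComparison(h=float(h), p=float(p), pairwise=pairwise)
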