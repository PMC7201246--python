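"""Individually customized panel (ICP) design from predicted neoepitopes.

A neoepitope candidate table has one row per (variant, peptide, HLA allele)
with a predicted IC50 binding affinity in nM. Panel design works at the
variant level: candidates are filtered at the 500 nM binding threshold,
collapsed to their coding variant (best affinity per variant), and the
strongest binders form the panel. Patients with at least 20 binder variants
get the top ``min(n, 30)``; patients below 20 get all their binders padded
with the highest-VAF remaining mutations up to 20 loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .filtering import add_variant_keys

#: canonical column set for a neoepitope candidate table
EPITOPE_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "peptide", "hla_allele", "ic50_nm", "rank_score"]

PANEL_MIN_LOCI = 20
PANEL_MAX_LOCI = 30


@dataclass
class PanelDesign:
    """Ordered ICP loci with provenance and repertoire coverage.

    ``loci`` is a DataFrame with columns chrom, pos, ref, alt, gene, vaf,
    rank_score and source (``neoantigen`` or ``vaf_filler``), in panel order.
    """

    patient_id: str
    loci: pd.DataFrame
    coverage_fraction: float | None = None

    @property
    def keys(self) -> list[str]:
        return list(add_variant_keys(self.loci)["key"])

    @property
    def genes(self) -> set[str]:
        return set(self.loci["gene"])

    def __len__(self) -> int:
        return len(self.loci)


def filter_binders(candidates: pd.DataFrame, threshold_nm: float = 500.0) -> pd.DataFrame:
    """Retain candidates with predicted IC50 strictly below *threshold_nm*,
    ordered by rank_score ascending (stable)."""
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be positive")
    kept = candidates.loc[candidates["ic50_nm"] < threshold_nm]
    return kept.sort_values("rank_score", kind="stable")


def _ordered_binder_variants(binders: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Collapse epitopes to unique variants (best rank_score per variant) and
    order by rank_score asc, VAF desc, then (chrom, pos, ref, alt)."""
    b = add_variant_keys(binders)
    best = b.sort_values("rank_score", kind="stable").drop_duplicates("key", keep="first")
    v = add_variant_keys(variants).set_index("key")
    best = best.set_index("key")
    best["vaf"] = v["vaf"]
    best = best.reset_index()
    return best.sort_values(
        ["rank_score", "vaf", "chrom", "pos", "ref", "alt"],
        ascending=[True, False, True, True, True, True],
        kind="stable",
    )

_LOCUS_COLS = ["chrom", "pos", "ref", "alt", "gene", "vaf", "rank_score", "source"]


def design_panel(
    binders: pd.DataFrame,
    all_variants: pd.DataFrame,
    patient_id: str = "",
    min_loci: int = PANEL_MIN_LOCI,
    max_loci: int = PANEL_MAX_LOCI,
) -> PanelDesign:
    """Build the ICP for one patient.

    With ``n`` unique binder variants: if ``n >= min_loci`` the panel is the
    top ``min(n, max_loci)`` by binding rank; otherwise all binder variants
    are taken and the panel is padded with the highest-VAF non-panel
    mutations until ``min_loci`` loci (or the variant list is exhausted).
    Deterministic: ties break by higher VAF then genomic coordinates.
    """
    if all_variants.empty:
        raise ValueError("all_variants is empty")
    ordered = _ordered_binder_variants(binders, all_variants) if len(binders) else pd.DataFrame(columns=_LOCUS_COLS + ["key"])
    n = len(ordered)
    if n >= min_loci:
        chosen = ordered.head(min(n, max_loci)).copy()
        chosen["source"] = "neoantigen"
    else:
        chosen = ordered.copy()
        chosen["source"] = "neoantigen"
        v = add_variant_keys(all_variants)
        fillers = v.loc[~v["key"].isin(set(chosen.get("key", pd.Series(dtype=object))))]
        fillers = fillers.sort_values(
            ["vaf", "chrom", "pos", "ref", "alt"],
            ascending=[False, True, True, True, True],
            kind="stable",
        ).head(max(0, min_loci - n)).copy()
        fillers["source"] = "vaf_filler"
        fillers["rank_score"] = float("nan")
        parts = [p[_LOCUS_COLS + ["key"]] for p in (chosen, fillers) if len(p)]
        chosen = pd.concat(parts, ignore_index=True) if parts else chosen
    loci = chosen[_LOCUS_COLS].reset_index(drop=True)
    return PanelDesign(patient_id=patient_id, loci=loci)


def coverage_fraction(panel: PanelDesign, predicted: pd.DataFrame) -> float:
    """Fraction of predicted neoepitopes whose coding variant is on the panel."""
    if predicted.empty:
        raise ValueError("predicted epitope table is empty")
    keys = set(panel.keys)
    pred = add_variant_keys(predicted)
    return float(pred["key"].isin(keys).mean())


def write_panel_bed(panel: PanelDesign, path, flank: int = 60) -> None:
    """Write panel loci as BED intervals (0-based half-open) of ``2*flank+1``
    bp centered on each locus, plus name and source columns."""
    with open(path, "w") as fh:
        for row in panel.loci.itertuples(index=False):
            start = max(0, int(row.pos) - 1 - flank)
            end = int(row.pos) + flank
            name = f"{row.gene}|{row.chrom}:{row.pos}:{row.ref}:{row.alt}"
            fh.write(f"{row.chrom}\t{start}\t{end}\t{name}\t0\t+\n")


def write_panel_manifest(panel: PanelDesign, path) -> None:
    """Write the panel as a TSV manifest (variant, gene, source, rank, VAF)."""
    panel.loci.to_csv(path, sep="\t", index=False)
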