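"""End-to-end orchestration: filter -> panel -> overlap -> kinetics -> outcomes.

A run is driven by a :class:`RunConfig` — either a simulation block (the
synthetic cohort generator) or paths to the real-input tables — plus the
named thresholds of every analysis rule, each defaulting to its standard
value (500 nM binders, 3%/1% VAF retention, 3-read detection, week-8
response at a 50% decline, 14-day pairing window). Every run writes its
stage outputs under ``outdir`` and a ``manifest.json`` recording the config
hash, seed and per-stage row counts; manifests are byte-identical across
repeated runs with the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from . import kinetics, outcomes as outcomes_mod, overlap as overlap_mod
from .filtering import call_clonality_table, compute_tmb, filter_variants
from .panel import coverage_fraction, design_panel, filter_binders, write_panel_bed, write_panel_manifest
from .sim import SimParams, simulate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and patient id."""

    def __init__(self, stage: str, patient_id: str | None, cause: Exception):
        self.stage, self.patient_id = stage, patient_id
        super().__init__(f"stage {stage!r} failed for patient {patient_id!r}: {cause}")


@dataclass
class RunConfig:
    outdir: str = "icptrack_run"
    seed: int = 0
    simulate: bool = True
    n_patients: int = 10
    # real-input paths (used when simulate is False)
    variants_path: str | None = None
    neoepitopes_path: str | None = None
    ctdna_path: str | None = None
    burden_path: str | None = None
    outcomes_path: str | None = None
    # thresholds (documented defaults)
    binder_nm: float = 500.0
    vaf_min: float = 0.03
    hotspot_vaf_min: float = 0.01
    coding_mb: float = 38.0
    min_alt_reads: int = 3
    response_week: int = 8
    ordering_week: int = 12
    decline_fraction: float = 0.5
    pairing_window_days: int = 14

    def __post_init__(self):
        if not 0 < self.decline_fraction < 1:
            raise ValueError("decline_fraction must be in (0, 1)")
        if self.binder_nm <= 0 or self.min_alt_reads < 0 or self.pairing_window_days < 0:
            raise ValueError("thresholds out of range")
        has_paths = self.variants_path is not None
        if self.simulate == has_paths:
            raise ValueError("exactly one of simulation mode or real-input paths must be configured")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` config file (# comments allowed)."""
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in casts:
                    raise ValueError(f"unknown config key {key!r}")
                if value.lower() in ("true", "false"):
                    kwargs[key] = value.lower() == "true"
                elif value.lower() in ("none", ""):
                    kwargs[key] = None
                else:
                    try:
                        kwargs[key] = int(value)
                    except ValueError:
                        try:
                            kwargs[key] = float(value)
                        except ValueError:
                            kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded, so
        the same run into two directories hashes identically)."""
        d = asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _load_inputs(config: RunConfig):
    """Return (variants by patient, neoepitopes by patient, ctdna, burden,
    outcomes) in either mode."""
    if config.simulate:
        params = SimParams(n_patients=config.n_patients, seed=config.seed)
        cohort = simulate_cohort(params, binder_threshold_nm=config.binder_nm)
        neo = cohort.neoepitopes
        return cohort.variants, neo, cohort.ctdna, cohort.burden, cohort.outcomes
    variants = io_mod.read_variants_tsv(config.variants_path)
    by_pid = {pid: sub.reset_index(drop=True) for pid, sub in variants.groupby("patient_id")}
    neo_df = pd.read_csv(config.neoepitopes_path, sep="\t")
    neo = {pid: sub.reset_index(drop=True) for pid, sub in neo_df.groupby("patient_id")}
    ctdna = io_mod.read_ctdna_csv(config.ctdna_path)
    burden = io_mod.read_burden_csv(config.burden_path)
    outc = io_mod.read_outcomes_csv(config.outcomes_path)
    return by_pid, neo, ctdna, burden, outc


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on every patient and return the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    variants, neo, ctdna, burden, outc = _load_inputs(config)
    if not variants:
        raise StageError("load", None, ValueError("empty patient list"))
    pids = sorted(variants)
    manifest["patients"] = pids
    io_mod.write_variants_tsv(pd.concat(variants.values(), ignore_index=True), out / "variants.tsv")
    io_mod.write_ctdna_csv(ctdna, out / "ctdna.csv")
    io_mod.write_burden_csv(burden, out / "burden.csv")
    manifest["stages"]["load"] = {"patients": len(pids), "variant_rows": int(sum(len(v) for v in variants.values()))}

    # --- filter + TMB + clonality -----------------------------------------
    retained, tmb = {}, {}
    for pid in pids:
        try:
            kept = filter_variants(
                variants[pid], vaf_min=config.vaf_min, hotspot_vaf_min=config.hotspot_vaf_min
            )
            retained[pid] = call_clonality_table(kept)
            tmb[pid] = compute_tmb(kept, config.coding_mb)
        except Exception as e:  # noqa: BLE001 - stage boundary
            raise StageError("filter", pid, e) from e
    pd.concat(retained.values(), ignore_index=True).to_csv(out / "retained.tsv", sep="\t", index=False)
    manifest["stages"]["filter"] = {
        "retained_rows": int(sum(len(v) for v in retained.values())),
        "tmb": {p: round(t, 4) for p, t in tmb.items()},
    }

    # --- panel design ------------------------------------------------------
    panels = {}
    for pid in pids:
        try:
            cand = neo.get(pid, pd.DataFrame())
            binders = filter_binders(cand, config.binder_nm) if len(cand) else cand
            p = design_panel(binders, retained[pid], patient_id=pid)
            if len(cand):
                p.coverage_fraction = coverage_fraction(p, cand)
            panels[pid] = p
            write_panel_manifest(p, out / f"panel_{pid}.tsv")
            write_panel_bed(p, out / f"panel_{pid}.bed")
        except Exception as e:  # noqa: BLE001
            raise StageError("panel", pid, e) from e
    manifest["stages"]["panel"] = {
        "sizes": {p: len(panels[p]) for p in pids},
        "coverage_fraction": {
            p: (round(panels[p].coverage_fraction, 4) if panels[p].coverage_fraction is not None else None)
            for p in pids
        },
    }

    # --- cohort overlap ----------------------------------------------------
    spectra = {pid: set(retained[pid]["gene"]) for pid in pids}
    try:
        summary = overlap_mod.cohort_overlap_summary(spectra)
        rec = overlap_mod.recurrence_stats(spectra)
    except Exception as e:  # noqa: BLE001
        raise StageError("overlap", None, e) from e
    summary.matrix.to_csv(out / "overlap_matrix.csv")
    overlap_json = {
        "median": round(summary.median, 4),
        "q1": round(summary.q1, 4),
        "q3": round(summary.q3, 4),
        "union_size": rec.union_size,
        "n_shared_ge2": rec.n_shared_ge2,
        "n_shared_gt3": rec.n_shared_gt3,
        "pct_ge2": rec.pct_ge2,
        "pct_gt3": rec.pct_gt3,
    }
    (out / "overlap_summary.json").write_text(json.dumps(overlap_json, sort_keys=True, indent=2))
    manifest["stages"]["overlap"] = overlap_json

    # --- ctDNA kinetics ----------------------------------------------------
    kin_rows, excluded = [], {}
    for pid in pids:
        try:
            series = ctdna.loc[ctdna["patient_id"] == pid]
            loci = panels[pid].keys
            if series.empty:
                excluded[pid] = "no ctDNA samples"
                continue
            rates = kinetics.detection_rates(series, loci, config.min_alt_reads)
            row = {
                "patient_id": pid,
                "baseline_rate": rates.baseline_rate,
                "ever_rate": rates.ever_rate,
            }
            try:
                fc = kinetics.fold_change(
                    series, loci, week=config.response_week,
                    window_days=config.pairing_window_days, min_alt_reads=config.min_alt_reads,
                )
            except ValueError as reason:
                excluded[pid] = str(reason)
                fc = None
            row["fold_change_week8"] = fc
            row["ctdna_class"] = (
                kinetics.classify_response(fc, config.decline_fraction) if fc is not None else None
            )
            try:
                row["fold_change_week12"] = kinetics.fold_change(
                    series, loci, week=config.ordering_week,
                    window_days=config.pairing_window_days, min_alt_reads=config.min_alt_reads,
                )
            except ValueError:
                row["fold_change_week12"] = None
            days = kinetics.sample_days(series)
            maf_series = [
                kinetics.mean_maf(series, d, loci, config.min_alt_reads) for d in days
            ]
            try:
                row["ctdna_time_to_half"] = kinetics.time_to_half(days, maf_series)
            except ValueError:
                row["ctdna_time_to_half"] = None
            pb = burden.loc[burden["patient_id"] == pid]
            if len(pb) >= 2 and pb["spd_mm2"].iloc[0] > 0:
                row["spd_time_to_half"] = kinetics.time_to_half(pb["day"], pb["spd_mm2"])
                conc = kinetics.burden_concordance(
                    series, pb, loci, config.pairing_window_days, config.min_alt_reads
                )
                row["r_per_locus"], row["r_mean"] = conc.r_per_locus, conc.r_mean
            kin_rows.append(row)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("kinetics", pid, e) from e
    kin = pd.DataFrame(kin_rows)
    kin.to_csv(out / "kinetics.csv", index=False)
    for pid, reason in excluded.items():
        logger.warning("patient %s excluded from fold-change summaries: %s", pid, reason)
    manifest["stages"]["kinetics"] = {
        "rows": len(kin),
        "excluded_from_fold_change": excluded,
        "n_responders": int((kin.get("ctdna_class") == "ctDNA_responder").sum()) if len(kin) else 0,
    }

    # --- outcomes ----------------------------------------------------------
    outcome_summary: dict = {}
    try:
        merged = outc.merge(kin[["patient_id", "ctdna_class", "fold_change_week12"]], on="patient_id", how="left")
        split = merged.dropna(subset=["ctdna_class"])
        if split["ctdna_class"].nunique() == 2:
            km = outcomes_mod.km_logrank(split)
            cox = outcomes_mod.cox_hr(split, reference="ctDNA_responder")
            outcome_summary = {
                "medians": {k: (None if math.isnan(v) or math.isinf(v) else v) for k, v in km.medians.items()},
                "logrank_p": round(km.p, 6),
                "hr": None if math.isnan(cox.hr) else round(cox.hr, 4),
                "hr_ci": [round(cox.ci_low, 4), None if math.isinf(cox.ci_high) else round(cox.ci_high, 4)],
                "separation": cox.separation,
            }
        else:
            outcome_summary = {"note": "fewer than two ctDNA classes; survival split skipped"}
        if "best_response" in merged.columns and merged["fold_change_week12"].notna().any():
            rep = outcomes_mod.response_ordering_report(merged, fc_col="fold_change_week12")
            rep.table.to_csv(out / "response_ordering.csv", index=False)
            outcome_summary["ordering_fisher_p"] = round(rep.fisher_p, 6)
    except Exception as e:  # noqa: BLE001
        raise StageError("outcomes", None, e) from e
    (out / "outcomes_summary.json").write_text(json.dumps(outcome_summary, sort_keys=True, indent=2))
    manifest["stages"]["outcomes"] = outcome_summary

    manifest_text = json.dumps(manifest, sort_keys=True, indent=2, default=_json_default)
    (out / "manifest.json").write_text(manifest_text)
    return manifest


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write a small bundled demo cohort (10 patients, all five scenarios)
    sized to run the full pipeline in well under a minute."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = SimParams(n_patients=10, seed=seed)
    cohort = simulate_cohort(params)
    io_mod.write_variants_tsv(pd.concat(cohort.variants.values(), ignore_index=True), out / "variants.tsv")
    neo = pd.concat(cohort.neoepitopes.values(), ignore_index=True)
    neo.to_csv(out / "neoepitopes.tsv", sep="\t", index=False)
    io_mod.write_ctdna_csv(cohort.ctdna, out / "ctdna.csv")
    io_mod.write_burden_csv(cohort.burden, out / "burden.csv")
    io_mod.write_outcomes_csv(cohort.outcomes, out / "outcomes.csv")
    scen = pd.DataFrame(sorted(cohort.scenarios.items()), columns=["patient_id", "scenario"])
    scen.to_csv(out / "scenarios.csv", index=False)
    cfg = (
        f"simulate = false\nseed = {seed}\noutdir = {out / 'run'}\n"
        f"variants_path = {out / 'variants.tsv'}\n"
        f"neoepitopes_path = {out / 'neoepitopes.tsv'}\n"
        f"ctdna_path = {out / 'ctdna.csv'}\n"
        f"burden_path = {out / 'burden.csv'}\n"
        f"outcomes_path = {out / 'outcomes.csv'}\n"
    )
    (out / "run.cfg").write_text(cfg)
    return {
        "dir": str(out),
        "config": str(out / "run.cfg"),
        "scenarios": dict(cohort.scenarios),
    }
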