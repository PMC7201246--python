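"""Serial ctDNA kinetics: detection, fold-change, response and concordance.

A ctDNA series is a long-format DataFrame with one row per (locus, day):
columns ``locus`` (variant key), ``day`` (days from first infusion),
``alt_reads``, ``depth`` and ``maf``. A tumor-burden series has one row per
surveillance scan: ``day`` and ``spd_mm2`` (sum of products of perpendicular
lesion diameters).

The clinically meaningful quantities:

* detection rates — the fraction of panel loci seen at baseline and at
  least once during treatment (a locus is detected when its alt read count
  reaches ``min_alt_reads``, default 3);
* mean MAF per draw, with undetected panel loci contributing 0;
* the week-8 fold-change of mean MAF versus baseline, classifying patients
  as ctDNA responders at a >= 50% decline;
* time to a 50% decline by linear interpolation between draws;
* Pearson (or Spearman) concordance between ctDNA level and radiological
  tumor burden after nearest-day pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CTDNA_COLUMNS = ["locus", "day", "alt_reads", "depth", "maf"]
DEFAULT_MIN_ALT_READS = 3


@dataclass(frozen=True)
class DetectionRates:
    baseline_rate: float | None  # None when no baseline draw exists
    ever_rate: float


def detection_rates(
    ctdna: pd.DataFrame,
    panel_loci: Sequence[str],
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> DetectionRates:
    """Fraction of panel loci detected at baseline (day 0) and ever."""
    loci = list(panel_loci)
    if not loci:
        raise ValueError("empty panel")
    detected = ctdna.loc[ctdna["alt_reads"] >= min_alt_reads]
    ever = detected["locus"].isin(loci)
    ever_rate = len(set(detected.loc[ever, "locus"])) / len(loci)
    if (ctdna["day"] == 0).any():
        base = detected.loc[(detected["day"] == 0) & ever, "locus"]
        baseline_rate = len(set(base)) / len(loci)
    else:
        baseline_rate = None
    return DetectionRates(baseline_rate=baseline_rate, ever_rate=ever_rate)


def mean_maf(
    ctdna: pd.DataFrame,
    day: int,
    panel_loci: Sequence[str],
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    detected_only: bool = False,
) -> float:
    """Mean MAF over the panel at one draw.

    Undetected or unmeasured panel loci contribute 0 by default (the
    declared zero-imputation convention); ``detected_only=True`` averages
    the detected loci instead and returns NaN when nothing is detected.
    """
    loci = list(panel_loci)
    rows = ctdna.loc[(ctdna["day"] == day) & ctdna["locus"].isin(loci)]
    if rows.empty and not (ctdna["day"] == day).any():
        raise ValueError(f"no ctDNA sample at day {day}")
    det = rows.loc[rows["alt_reads"] >= min_alt_reads]
    if detected_only:
        return float(det["maf"].mean()) if len(det) else float("nan")
    return float(det["maf"].sum() / len(loci))


def sample_days(ctdna: pd.DataFrame) -> list:
    return sorted(ctdna["day"].unique())


def nearest_day(days: Sequence[float], target: float, window: float) -> float | None:
    """Nearest sampled day within +-*window* of *target*; ties go to the
    earlier day. None when no day qualifies."""
    best = None
    for d in sorted(days):
        dist = abs(d - target)
        if dist <= window and (best is None or dist < abs(best - target)):
            best = d
    return best


def fold_change(
    ctdna: pd.DataFrame,
    panel_loci: Sequence[str],
    week: int = 8,
    window_days: int = 14,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> float | None:
    """Mean-MAF fold-change from baseline to the draw nearest day 7*week.

    Returns None when no draw falls inside the window; raises when there is
    no baseline draw or the baseline mean MAF is 0 (fold-change undefined —
    such patients are excluded from cohort summaries).
    """
    days = sample_days(ctdna)
    if 0 not in days:
        raise ValueError("no baseline (day 0) ctDNA draw")
    base = mean_maf(ctdna, 0, panel_loci, min_alt_reads)
    if base == 0:
        raise ValueError("baseline mean MAF is 0: fold-change undefined")
    day = nearest_day(days, 7 * week, window_days)
    if day is None:
        logger.info("no ctDNA draw within %d days of week %d", window_days, week)
        return None
    return mean_maf(ctdna, day, panel_loci, min_alt_reads) / base


def classify_response(fc_week8: float, decline_fraction: float = 0.5) -> str:
    """ctDNA responder at a >= 50% decline of mean MAF by week 8 (inclusive:
    a fold-change of exactly 0.5 is a response)."""
    return "ctDNA_responder" if fc_week8 <= decline_fraction else "ctDNA_nonresponder"


def time_to_half(days: Sequence[float], values: Sequence[float]) -> float | None:
    """First day the series crosses half its baseline, by linear
    interpolation between consecutive points; None if never ("not reached")."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(days) < 2:
        raise ValueError("need at least two points")
    if values[0] <= 0:
        raise ValueError("baseline value must be positive")
    half = 0.5 * values[0]
    for i in range(1, len(values)):
        if values[i] <= half:
            if values[i] == half or values[i - 1] == values[i]:
                return float(days[i])
            # previous point is above the threshold; interpolate the crossing
            frac = (values[i - 1] - half) / (values[i - 1] - values[i])
            return float(days[i - 1] + frac * (days[i] - days[i - 1]))
    return None


@dataclass(frozen=True)
class Concordance:
    r_per_locus: float  # pooled over (locus, paired day) MAF vs SPD
    r_mean: float  # per-day mean MAF vs SPD
    n_pairs: int


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def burden_concordance(
    ctdna: pd.DataFrame,
    burden: pd.DataFrame,
    panel_loci: Sequence[str],
    pairing_window_days: int = 14,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    method: str = "pearson",
) -> Concordance:
    """Correlation between ctDNA level and SPD tumor burden.

    Each surveillance scan is paired with the ctDNA draw nearest in time
    (within the window). Reported both per locus (pooled points) and at the
    per-day mean-MAF level; NaN when fewer than 3 pairs or zero variance.
    """
    days = sample_days(ctdna)
    mean_x, mean_y, loc_x, loc_y = [], [], [], []
    for row in burden.itertuples(index=False):
        d = nearest_day(days, row.day, pairing_window_days)
        if d is None:
            continue
        mean_x.append(mean_maf(ctdna, d, panel_loci, min_alt_reads))
        mean_y.append(row.spd_mm2)
        draw = ctdna.loc[(ctdna["day"] == d) & ctdna["locus"].isin(list(panel_loci))]
        loc_x.extend(draw["maf"].tolist())
        loc_y.extend([row.spd_mm2] * len(draw))
    return Concordance(
        r_per_locus=_corr(np.asarray(loc_x), np.asarray(loc_y), method),
        r_mean=_corr(np.asarray(mean_x), np.asarray(mean_y), method),
        n_pairs=len(mean_x),
    )


@dataclass(frozen=True)
class PairedTimeComparison:
    mean_a: float
    mean_b: float
    t: float
    p: float
    degenerate: bool  # zero-variance differences


def paired_time_comparison(times_a: Sequence[float], times_b: Sequence[float]) -> PairedTimeComparison:
    """Two-tailed paired Student's t test on matched time-to-event values
    (e.g. ctDNA vs radiological time to 50% decline per patient).

    Zero-variance differences are handled explicitly: all-zero differences
    give t = 0, p = 1; a constant nonzero difference is reported with
    ``t = +-inf``, p at the floor and the degenerate flag set.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length paired lists with n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return PairedTimeComparison(float(a.mean()), float(b.mean()), 0.0, 1.0, True)
        t = np.inf if d[0] > 0 else -np.inf
        return PairedTimeComparison(float(a.mean()), float(b.mean()), float(t), float(np.finfo(float).tiny), True)
    t, p = stats.ttest_rel(a, b)
    return PairedTimeComparison(float(a.mean()), float(b.mean()), float(t), float(p), False)
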