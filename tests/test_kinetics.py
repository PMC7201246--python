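"""ctDNA kinetics: detection, fold-change, interpolation, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icptrack.kinetics import (
    burden_concordance,
    classify_response,
    detection_rates,
    fold_change,
    mean_maf,
    nearest_day,
    paired_time_comparison,
    time_to_half,
)


def series(rows):
    return pd.DataFrame(rows, columns=["locus", "day", "alt_reads", "depth", "maf"])


def make_series(maf_by_day, depth=1000):
    rows = []
    for day, mafs in maf_by_day.items():
        for locus, m in mafs.items():
            rows.append([locus, day, round(m * depth), depth, m])
    return series(rows)


LOCI = ["L1", "L2", "L3"]


def test_detection_rates_examples_and_oracle():
    s = make_series({0: {"L1": 0.1, "L2": 0.2, "L3": 0.05}})
    r = detection_rates(s, LOCI)
    assert (r.baseline_rate, r.ever_rate) == (1.0, 1.0)
    none = make_series({0: {"L1": 0.0, "L2": 0.0, "L3": 0.0}})
    r = detection_rates(none, LOCI)
    assert (r.baseline_rate, r.ever_rate) == (0.0, 0.0)
    # random detection matrix vs column-wise any / first-row oracle
    rng = np.random.default_rng(2)
    days = [0, 28, 56]
    mat = rng.random((len(days), 10)) < 0.4  # detected flags
    loci = [f"M{i}" for i in range(10)]
    rows = []
    for di, day in enumerate(days):
        for li, locus in enumerate(loci):
            alt = 5 if mat[di, li] else 0
            rows.append([locus, day, alt, 100, alt / 100])
    r = detection_rates(series(rows), loci)
    assert r.baseline_rate == pytest.approx(mat[0].mean())
    assert r.ever_rate == pytest.approx(mat.any(axis=0).mean())
    assert r.ever_rate >= r.baseline_rate


def test_detection_without_baseline_draw():
    s = make_series({28: {"L1": 0.1, "L2": 0.0, "L3": 0.0}})
    r = detection_rates(s, LOCI)
    assert r.baseline_rate is None
    assert r.ever_rate == pytest.approx(1 / 3)


def test_mean_maf_zero_imputes_undetected():
    s = make_series({0: {"L1": 0.10, "L2": 0.20, "L3": 0.0}})
    assert mean_maf(s, 0, LOCI) == pytest.approx(0.10)
    assert mean_maf(s, 0, LOCI, detected_only=True) == pytest.approx(0.15)
    allzero = make_series({0: {l: 0.0 for l in LOCI}})
    assert mean_maf(allzero, 0, LOCI) == 0.0
    rng = np.random.default_rng(4)
    mafs = {f"M{i}": float(rng.uniform(0, 0.2)) for i in range(8)}
    s = make_series({0: mafs}, depth=10000)
    loci = list(mafs)
    expected = np.mean([m if round(m * 10000) >= 3 else 0.0 for m in mafs.values()])
    assert mean_maf(s, 0, loci) == pytest.approx(expected)
    with pytest.raises(ValueError):
        mean_maf(s, 99, loci)


def test_fold_change_examples_and_tie_break():
    s = make_series({0: {"L1": 0.20}, 56: {"L1": 0.05}})
    assert fold_change(s, ["L1"]) == pytest.approx(0.25)
    ident = make_series({0: {"L1": 0.20}, 56: {"L1": 0.20}})
    assert fold_change(ident, ["L1"]) == pytest.approx(1.0)
    # draws at 49 and 63 are equidistant from day 56: earlier one wins
    tie = make_series({0: {"L1": 0.20}, 49: {"L1": 0.10}, 63: {"L1": 0.30}})
    assert fold_change(tie, ["L1"]) == pytest.approx(0.5)
    assert nearest_day([0, 49, 63], 56, 14) == 49
    # no draw in the window
    sparse = make_series({0: {"L1": 0.20}, 120: {"L1": 0.05}})
    assert fold_change(sparse, ["L1"]) is None
    # zero baseline is undefined
    zero = make_series({0: {"L1": 0.0}, 56: {"L1": 0.05}})
    with pytest.raises(ValueError, match="undefined"):
        fold_change(zero, ["L1"])


def test_fold_change_scale_invariance():
    rng = np.random.default_rng(6)
    mafs0 = {f"M{i}": float(rng.uniform(0.05, 0.3)) for i in range(5)}
    mafs56 = {k: v * 0.4 for k, v in mafs0.items()}
    s = make_series({0: mafs0, 56: mafs56}, depth=100000)
    f1 = fold_change(s, list(mafs0))
    scaled = s.copy()
    scaled["maf"] *= 3.0
    scaled["alt_reads"] *= 3.0
    f2 = fold_change(scaled, list(mafs0))
    assert f1 == pytest.approx(f2)


def test_classify_response_inclusive_boundary():
    assert classify_response(0.49) == "ctDNA_responder"
    assert classify_response(0.50) == "ctDNA_responder"  # >=50% decline inclusive
    assert classify_response(1.4) == "ctDNA_nonresponder"


def test_time_to_half_interpolation_by_hand():
    # crossing 0.10 between (0, 0.20) and (28, 0.08): 28 * (0.20-0.10)/(0.20-0.08)
    assert time_to_half([0, 28], [0.20, 0.08]) == pytest.approx(28 * (0.10 / 0.12))
    assert time_to_half([0, 28], [0.2, 0.1]) == pytest.approx(28.0)  # exact sample
    assert time_to_half([0, 28, 56], [0.1, 0.2, 0.3]) is None  # never crosses
    with pytest.raises(ValueError):
        time_to_half([0, 28], [0.0, 0.1])


def test_burden_concordance_degenerate_and_linear():
    days = [0, 28, 56, 84]
    mafs = {d: {"L1": 0.2 * (0.8 ** (d / 28)), "L2": 0.1 * (0.8 ** (d / 28))} for d in days}
    s = make_series(mafs, depth=100000)
    spd = [3000 * (0.8 ** (d / 28)) for d in days]
    burden = pd.DataFrame({"day": days, "spd_mm2": spd})
    c = burden_concordance(s, burden, ["L1", "L2"], pairing_window_days=0)
    assert c.r_mean == pytest.approx(1.0, abs=1e-6)
    assert c.n_pairs == 4
    # constant MAF: zero variance, correlation undefined
    const = make_series({d: {"L1": 0.1, "L2": 0.1} for d in days})
    c2 = burden_concordance(const, burden, ["L1", "L2"], pairing_window_days=0)
    assert np.isnan(c2.r_mean)


def test_burden_concordance_matches_pearson_oracle():
    rng = np.random.default_rng(9)
    days = [0, 28, 56, 84, 126]
    mafs = {d: {"L1": float(rng.uniform(0.02, 0.3))} for d in days}
    s = make_series(mafs, depth=100000)
    burden = pd.DataFrame({"day": days, "spd_mm2": rng.uniform(1000, 5000, size=len(days))})
    c = burden_concordance(s, burden, ["L1"], pairing_window_days=0)
    x = [mean_maf(s, d, ["L1"]) for d in days]
    r_exp = stats.pearsonr(x, burden["spd_mm2"]).statistic
    assert c.r_mean == pytest.approx(r_exp)


def test_paired_time_comparison_paths():
    same = paired_time_comparison([10, 20, 30], [10, 20, 30])
    assert same.t == 0.0 and same.p == 1.0 and same.degenerate
    const = paired_time_comparison([20, 30, 40], [70, 80, 90])
    assert const.degenerate and const.t == -np.inf and const.p < 1e-300
    # non-degenerate triple vs the closed form on the differences
    a, b = [20.0, 35.0, 40.0], [70.0, 80.0, 95.0]
    res = paired_time_comparison(a, b)
    d = np.array(a) - np.array(b)
    t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p_exp = 2 * stats.t.sf(abs(t_exp), df=len(d) - 1)
    assert res.t == pytest.approx(t_exp)
    assert res.p == pytest.approx(p_exp)
    assert not res.degenerate
    with pytest.raises(ValueError):
        paired_time_comparison([1.0], [2.0])
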