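"""Accuracy metrics, gain survey, decay fit, coverage and correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from pkscan import (
    BasePair,
    FitError,
    FixtureSpec,
    GainSampleSpec,
    Implant,
    accuracy_vs_length,
    adjacent_extension_probability,
    connecting_probability,
    cumulative_coverage,
    fit_exponential_decay,
    generate_corpus,
    generate_structure,
    mfe_gain_survey,
    sample_gains,
    score_prediction,
    single_pair_probability,
)
from pkscan.stats import AccuracyReport


def test_pairing_combinatorics_exact():
    assert single_pair_probability() == 6 / 16 == 0.375
    assert adjacent_extension_probability() == 39 / 64


@pytest.mark.parametrize("pred,truth,tpr,ppv", [
    ({(0, 5), (1, 4)}, {(0, 5), (1, 4)}, 1.0, 1.0),
    (set(), {(0, 5)}, 0.0, math.nan),
    ({(0, 5), (1, 4), (2, 3)}, {(0, 5), (1, 4), (7, 9), (8, 10)}, 0.5, 2 / 3),
])
def test_score_prediction_arithmetic(pred, truth, tpr, ppv):
    rep = score_prediction(pred, truth)
    assert rep.tp + rep.fn == len(truth)
    assert rep.tp + rep.fp == len(pred)
    assert rep.tpr == pytest.approx(tpr) if not math.isnan(tpr) else not rep.tpr_defined
    if math.isnan(ppv):
        assert not rep.ppv_defined
    else:
        assert rep.ppv == pytest.approx(ppv)


def test_score_prediction_averages_cooptimals():
    truth = {(0, 9), (1, 8)}
    rep = score_prediction([{(0, 9), (1, 8)}, {(0, 9)}], truth)
    assert rep.averaged_over == 2
    assert rep.tpr == pytest.approx((1.0 + 0.5) / 2)
    assert rep.ppv == pytest.approx(1.0)
    # undefined PPV of an empty co-optimal is excluded from the average
    rep2 = score_prediction([{(0, 9)}, set()], truth)
    assert rep2.ppv == pytest.approx(1.0) and rep2.tpr == pytest.approx(0.25)


def test_survey_single_section_is_empty(hairpin, params):
    table = mfe_gain_survey([hairpin], params)
    assert table.empty


def test_survey_counts_and_connected_flag(params):
    fix = generate_structure(FixtureSpec(seed=50), params)
    table = mfe_gain_survey([("m", fix.structure)], params)
    n = len(fix.sections)
    assert len(table) <= n * (n - 1) // 2
    conn = table[table["connected"]]
    assert len(conn) == 1 and conn["gain"].iloc[0] > 0
    assert (table["gain"] == table["mfe"].abs()).all()


def test_fit_recovers_exact_geometric_histogram():
    # counts exactly halve per bin: decay rate ln 2, probability 1/2
    gains = [float(k) for k in range(8) for _ in range(2 ** (10 - k))]
    fit = fit_exponential_decay(gains, bin_width=1.0)
    assert fit.a == pytest.approx(math.log(2), abs=1e-12)
    assert fit.pairing_probability == pytest.approx(0.5, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_constant_histogram_degenerate():
    gains = [float(k) for k in range(6) for _ in range(50)]
    fit = fit_exponential_decay(gains)
    assert fit.a == pytest.approx(0.0, abs=1e-12)
    assert fit.pairing_probability == pytest.approx(1.0)


def test_fit_needs_three_bins():
    with pytest.raises(FitError):
        fit_exponential_decay([1.0] * 100 + [2.0] * 50)


def test_fit_recovers_generating_probability_monte_carlo():
    p0 = 39 / 64
    gains = sample_gains(GainSampleSpec(seed=99, n=100_000, p0=p0))
    fit = fit_exponential_decay(gains, bin_width=1.0)
    assert fit.pairing_probability == pytest.approx(p0, abs=0.02)


def test_connecting_probability_hand_counts():
    table = pd.DataFrame({
        "molecule": ["m"] * 10,
        "sec_i": range(10),
        "sec_j": range(1, 11),
        "mfe": [-g for g in [0.2, 0.4, 0.6, 1.2, 1.4, 1.6, 1.8, 2.2, 2.4, 2.6]],
        "gain": [0.2, 0.4, 0.6, 1.2, 1.4, 1.6, 1.8, 2.2, 2.4, 2.6],
        "connected": [False, False, True, True, True, False, True, True, True, True],
        "admissible": [True] * 10,
    })
    curve = connecting_probability(table, bin_width=1.0)
    assert curve["probability"].tolist() == [1 / 3, 3 / 4, 1.0]
    assert curve["total"].tolist() == [3, 4, 3]


def test_connecting_probability_extremes():
    base = {"molecule": "m", "sec_i": 0, "sec_j": 1, "admissible": True}
    all_conn = pd.DataFrame([{**base, "mfe": -1.1, "gain": 1.1, "connected": True}] * 4)
    assert connecting_probability(all_conn)["probability"].tolist() == [1.0]
    none_conn = pd.DataFrame([{**base, "mfe": -1.1, "gain": 1.1, "connected": False}] * 4)
    assert connecting_probability(none_conn)["probability"].tolist() == [0.0]


def test_cumulative_coverage_monotone_to_one():
    rng = np.random.default_rng(2)
    table = pd.DataFrame({
        "molecule": ["m"] * 50,
        "sec_i": range(50),
        "sec_j": range(1, 51),
        "gain": rng.uniform(0, 10, 50),
        "connected": rng.random(50) < 0.3,
        "mfe": 0.0,
        "admissible": True,
    })
    if not table["connected"].any():
        table.loc[0, "connected"] = True
    curve = cumulative_coverage(table)
    cov = curve["coverage"].to_numpy()
    assert (np.diff(cov) >= -1e-12).all()
    assert cov[-1] == pytest.approx(1.0)


def test_cumulative_coverage_concentrates_on_implants(params):
    spec = FixtureSpec(seed=60, n_hairpins=3, implants=(
        Implant("2cluster", 6, "perfect"), Implant("decoy", 4, "perfect")))
    corpus = generate_corpus(spec, 12, params)
    table = mfe_gain_survey(
        [(f"m{i}", f.structure) for i, f in enumerate(corpus)], params)
    curve = cumulative_coverage(table)
    top10 = curve[curve["top_fraction"] <= 0.10]
    assert top10["coverage"].iloc[-1] > 0.9


def test_accuracy_vs_length_perfect_and_flagged():
    reps = [AccuracyReport(1, 0, 0, t, t) for t in (0.2, 0.4, 0.6, 0.8)]
    out = accuracy_vs_length(reps, [100, 200, 300, 400])
    assert out.r_tpr == pytest.approx(1.0)
    const = [AccuracyReport(1, 0, 0, 0.5, 0.5) for _ in range(4)]
    flagged = accuracy_vs_length(const, [100, 200, 300, 400])
    assert not flagged.tpr_defined and not flagged.ppv_defined


def test_accuracy_vs_length_hand_pearson():
    # closed form for x=[1,2,3,4], y=[0.1,0.4,0.2,0.5]: r = 1/sqrt(2)
    reps = [AccuracyReport(1, 0, 0, y, y) for y in (0.1, 0.4, 0.2, 0.5)]
    out = accuracy_vs_length(reps, [1, 2, 3, 4])
    assert out.r_tpr == pytest.approx(1 / math.sqrt(2))
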