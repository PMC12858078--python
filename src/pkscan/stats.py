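"""Survey statistics and accuracy metrics for section-pair analyses.

Covers base-pair prediction accuracy (TPR = TP/(TP+FN), PPV = TP/(TP+FP),
averaged over co-optimal structures when several exist), the MFE-gain survey
over all admissible section pairs of a corpus, the exponential fit

    frequency ∝ exp(-a * MFE gain)

whose decay rate yields the per-base-pair pairing probability exp(-a * 1.0)
(each pair contributing ~1 kcal/mol), the connecting-probability curve
(connected / all section pairs per MFE-gain bin), top-K cumulative coverage
of connected pairs ranked by gain, and the accuracy-vs-length correlation
check.

Pairing combinatorics of the canonical alphabet are exposed as exact helpers:
with 6 canonical pair types among the 16 ordered base combinations, a random
base pair is pairable with probability 6/16 = 3/8, and at least one of two
adjacent candidate extensions of a helix is pairable with probability
1 - (5/8)^2 = 39/64.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .duplex import section_pair_mfe
from .structures import BasePair, PseudoknottedStructure, identify_sections
from .clusters import build_section_graph
from .thermo import NNParameterSet

__all__ = [
    "AccuracyReport",
    "DecayFit",
    "FitError",
    "score_prediction",
    "mfe_gain_survey",
    "fit_exponential_decay",
    "connecting_probability",
    "cumulative_coverage",
    "accuracy_vs_length",
    "single_pair_probability",
    "adjacent_extension_probability",
]


def single_pair_probability() -> float:
    """Probability that two uniform random bases form a canonical pair: 6/16."""
    return float(Fraction(6, 16))


def adjacent_extension_probability() -> float:
    """Probability that at least one of the two adjacent candidate positions
    can extend an existing helix: 1 - (1 - 3/8)^2 = 39/64."""
    p = Fraction(6, 16)
    return float(1 - (1 - p) ** 2)


@dataclass
class AccuracyReport:
    tp: float
    fp: float
    fn: float
    tpr: float  # nan when TP+FN = 0
    ppv: float  # nan when TP+FP = 0
    averaged_over: int = 1

    @property
    def tpr_defined(self) -> bool:
        return not math.isnan(self.tpr)

    @property
    def ppv_defined(self) -> bool:
        return not math.isnan(self.ppv)


def _score_single(predicted: set[BasePair], truth: set[BasePair]) -> AccuracyReport:
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tpr = tp / (tp + fn) if tp + fn else math.nan
    ppv = tp / (tp + fp) if tp + fp else math.nan
    return AccuracyReport(tp, fp, fn, tpr, ppv)


def score_prediction(
    predicted: Iterable[BasePair] | Sequence[Iterable[BasePair]],
    truth: Iterable[BasePair],
) -> AccuracyReport:
    """Exact set accuracy of predicted vs reference base pairs.

    ``predicted`` may be a single pair set or a list of co-optimal pair sets;
    in the latter case metrics are computed per structure and averaged, with
    undefined values excluded from their average.
    """
    truth = {BasePair(*p) for p in truth}
    preds = list(predicted)
    if preds and not isinstance(preds[0], (tuple, BasePair)):
        sets = [{BasePair(*p) for p in s} for s in preds]
    else:
        sets = [{BasePair(*p) for p in preds}]
    if not sets:
        sets = [set()]
    reports = [_score_single(s, truth) for s in sets]
    if len(reports) == 1:
        return reports[0]

    def _avg(vals: list[float]) -> float:
        vals = [v for v in vals if not math.isnan(v)]
        return sum(vals) / len(vals) if vals else math.nan

    return AccuracyReport(
        tp=_avg([r.tp for r in reports]),
        fp=_avg([r.fp for r in reports]),
        fn=_avg([r.fn for r in reports]),
        tpr=_avg([r.tpr for r in reports]),
        ppv=_avg([r.ppv for r in reports]),
        averaged_over=len(reports),
    )


SURVEY_COLUMNS = ["molecule", "sec_i", "sec_j", "mfe", "gain", "connected", "admissible"]


def mfe_gain_survey(
    corpus: Iterable[PseudoknottedStructure | tuple[str, PseudoknottedStructure]],
    params: NNParameterSet,
) -> pd.DataFrame:
    """One row per admissible section pair per molecule: MFE, gain = |MFE|,
    and whether the reference structure actually connects the pair."""
    rows = []
    for k, item in enumerate(corpus):
        mol, structure = item if isinstance(item, tuple) else (f"seq{k:04d}", item)
        sections = identify_sections(structure)
        truth_edges = build_section_graph(structure, sections).edges
        for a in range(len(sections)):
            for b in range(a + 1, len(sections)):
                s1, s2 = sections[a], sections[b]
                if s1.loop_id == s2.loop_id:
                    continue
                res = section_pair_mfe(
                    structure.sequence, s1, s2, params, traceback=False)
                rows.append({
                    "molecule": mol,
                    "sec_i": a,
                    "sec_j": b,
                    "mfe": res.mfe,
                    "gain": res.gain,
                    "connected": (a, b) in truth_edges,
                    "admissible": True,
                })
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


class FitError(ValueError):
    """Not enough populated histogram bins to fit the decay."""


@dataclass
class DecayFit:
    a: float  # decay rate per kcal/mol
    pairing_probability: float  # exp(-a * 1.0 kcal/mol)
    bin_width: float
    r_squared: float
    n_bins: int


def fit_exponential_decay(
    gains: Sequence[float],
    bin_width: float = 1.0,
    min_count: int = 5,
) -> DecayFit:
    """Weighted least-squares fit of log(frequency) vs MFE gain.

    Gains are histogrammed at ``bin_width`` (kcal/mol); bins with fewer than
    ``min_count`` observations are excluded; weights are sqrt(count), the
    Poisson weighting for log counts.  Returns the decay rate a and the
    implied per-pair pairing probability exp(-a).
    """
    gains = np.asarray(list(gains), dtype=float)
    if gains.size == 0:
        raise FitError("no gains to fit")
    edges = np.arange(0.0, gains.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(gains, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts >= min_count
    if keep.sum() < 3:
        raise FitError(f"need >= 3 bins with >= {min_count} counts, have {keep.sum()}")
    x, y = centers[keep], np.log(counts[keep].astype(float))
    wts = np.sqrt(counts[keep].astype(float))
    slope, intercept = np.polyfit(x, y, 1, w=wts)
    resid = y - (slope * x + intercept)
    ybar = np.average(y, weights=wts**2)
    ss_res = float(np.sum((wts * resid) ** 2))
    ss_tot = float(np.sum((wts * (y - ybar)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    a = float(-slope)
    return DecayFit(a, math.exp(-a), bin_width, r2, int(keep.sum()))


def connecting_probability(table: pd.DataFrame, bin_width: float = 1.0) -> pd.DataFrame:
    """Per-MFE-gain-bin ratio of connected to all section pairs.

    Empty bins are omitted (not zero-filled); columns: bin_left, bin_right,
    total, connected, probability.
    """
    if table.empty:
        raise ValueError("empty survey table")
    gains = table["gain"].to_numpy()
    idx = np.floor(gains / bin_width).astype(int)
    out = []
    for b in sorted(set(idx)):
        in_bin = table[idx == b]
        total = len(in_bin)
        conn = int(in_bin["connected"].sum())
        out.append({
            "bin_left": b * bin_width,
            "bin_right": (b + 1) * bin_width,
            "total": total,
            "connected": conn,
            "probability": conn / total,
        })
    return pd.DataFrame(out)


def cumulative_coverage(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of connected section pairs covered by the top-K pairs ranked
    by MFE gain (descending; ties broken by molecule id then pair indices).

    The curve is monotone nondecreasing and ends at exactly 1.0.
    """
    if table.empty:
        raise ValueError("empty survey table")
    n_connected = int(table["connected"].sum())
    if n_connected == 0:
        raise ValueError("no connected section pairs to cover")
    ranked = table.sort_values(
        ["gain", "molecule", "sec_i", "sec_j"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    covered = ranked["connected"].cumsum() / n_connected
    return pd.DataFrame({
        "k": np.arange(1, len(ranked) + 1),
        "top_fraction": np.arange(1, len(ranked) + 1) / len(ranked),
        "coverage": covered.to_numpy(dtype=float),
    })


@dataclass
class LengthCorrelation:
    r_tpr: float
    p_tpr: float
    r_ppv: float
    p_ppv: float
    tpr_defined: bool
    ppv_defined: bool


def accuracy_vs_length(
    reports: Sequence[AccuracyReport], lengths: Sequence[int]
) -> LengthCorrelation:
    """Pearson correlation (two-sided p) of per-sequence TPR and PPV against
    sequence length; constant metric vectors are flagged undefined."""
    if len(reports) != len(lengths) or len(reports) < 3:
        raise ValueError("need >= 3 (report, length) pairs")
    lengths = np.asarray(lengths, dtype=float)

    def _corr(vals: np.ndarray) -> tuple[float, float, bool]:
        ok = ~np.isnan(vals)
        if ok.sum() < 3 or np.std(vals[ok]) == 0 or np.std(lengths[ok]) == 0:
            return math.nan, math.nan, False
        r, p = sps.pearsonr(vals[ok], lengths[ok])
        return float(r), float(p), True

    tprs = np.array([r.tpr for r in reports])
    ppvs = np.array([r.ppv for r in reports])
    r_t, p_t, ok_t = _corr(tprs)
    r_p, p_p, ok_p = _corr(ppvs)
    return LengthCorrelation(r_t, p_t, r_p, p_p, ok_t, ok_p)
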