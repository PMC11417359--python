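"""Trend-anomaly statistics between two samples along inferred time.

For every driver gene, nascent (unspliced, kNN-smoothed) mRNA levels are
ordered by each sample's inferred cell time and tested with the
Mann–Kendall trend test.  A gene is called anomalous in the perturbed
sample when a real wild-type trend (P below ``alpha``) either reverses
sign in the knockout or flattens by more than a slope-ratio threshold
(OLS slopes on ordinal position scaled to [0, 1]).  The anomaly type
follows the wild-type direction: repression anomaly for genes whose
nascent mRNA falls across the stage, induction anomaly for rising genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MKResult",
    "TrendCall",
    "mann_kendall",
    "trend_slope",
    "classify_trend",
    "summarize_classification",
]

MIN_SERIES_LEN = 8

LABELS = ("repression_anomaly", "induction_anomaly", "unchanged")


@dataclass
class MKResult:
    """Mann–Kendall statistics for one ordered series."""

    S: int
    varS: float
    z: float
    p: float
    slope: float
    n: int
    testable: bool = True


@dataclass
class TrendCall:
    gene_id: str
    direction: str  # repression | induction (from WT)
    mk_wt: MKResult
    mk_ko: MKResult
    slope_ratio: float
    label: str
    audit_flag: str = ""


def mann_kendall(values) -> MKResult:
    """Mann–Kendall test: S = sum of signs of all forward differences.

    Variance uses the tie correction
    varS = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 over tie groups; the
    z statistic applies the continuity correction (S -/+ 1)/sqrt(varS),
    zero when S is zero; p is two-sided normal.  Series shorter than 3
    are untestable and get p = 1 by convention.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    slope = trend_slope(x) if n >= 2 else 0.0
    if n < 3:
        return MKResult(S=0, varS=0.0, z=0.0, p=1.0, slope=slope, n=n, testable=False)

    diff_sign = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff_sign, k=1).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    varS = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0

    if S == 0 or varS <= 0:
        z = 0.0
    elif S > 0:
        z = (S - 1) / np.sqrt(varS)
    else:
        z = (S + 1) / np.sqrt(varS)
    p = 1.0 if z == 0 else float(2.0 * norm.sf(abs(z)))
    return MKResult(S=S, varS=float(varS), z=float(z), p=min(p, 1.0), slope=slope, n=n)


def trend_slope(values) -> float:
    """OLS slope of the series on ordinal position rescaled to [0, 1]."""
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("trend_slope needs at least 2 values")
    x = np.arange(n) / (n - 1)
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def classify_trend(
    gene_id: str,
    series_wt,
    series_ko,
    direction: str | None = None,
    alpha: float = 0.01,
    ratio_threshold: float = 4.0,
    eps: float | None = None,
    gate: str = "wt",
    trend_change: str = "sign",
) -> TrendCall | None:
    """Three-way anomaly call for one gene.

    The significance gate (default: the WT series, which establishes the
    real trend a perturbation can deviate from; configurable to 'ko' or
    'both') must pass at ``alpha``; the gene is anomalous when the trend
    changes between samples (sign of S reverses; 'significance' mode
    instead requires the KO trend to lose significance) or when the
    slope ratio |slope_WT| / max(|slope_KO|, eps) exceeds
    ``ratio_threshold``.  Anything else — including untestable series —
    is 'unchanged'.  ``direction`` defaults to the sign of the WT trend;
    genes without an interpretable WT direction (gate not passed) return
    None (excluded as direction-undefined).
    """
    wt = np.asarray(series_wt, dtype=float)
    ko = np.asarray(series_ko, dtype=float)
    mk_wt = mann_kendall(wt)
    mk_ko = mann_kendall(ko)

    if wt.size < MIN_SERIES_LEN or ko.size < MIN_SERIES_LEN:
        return TrendCall(
            gene_id, direction or "undefined", mk_wt, mk_ko, 0.0, "unchanged",
            audit_flag="untestable_series",
        )

    if eps is None:
        rng = float(wt.max() - wt.min())
        eps = 1e-6 * (rng if rng > 0 else 1.0)
    slope_ratio = abs(mk_wt.slope) / max(abs(mk_ko.slope), eps)

    if direction is None:
        if mk_wt.p >= alpha or mk_wt.S == 0:
            return None  # direction-undefined: no interpretable WT trend
        direction = "repression" if mk_wt.S < 0 else "induction"

    gates = {
        "wt": mk_wt.p < alpha,
        "ko": mk_ko.p < alpha,
        "both": mk_wt.p < alpha and mk_ko.p < alpha,
    }
    if gate not in gates:
        raise ValueError(f"unknown gate {gate!r}")

    if trend_change == "sign":
        changed = np.sign(mk_wt.S) != np.sign(mk_ko.S)
    elif trend_change == "significance":
        changed = mk_ko.p >= alpha
    else:
        raise ValueError(f"unknown trend_change mode {trend_change!r}")

    if gates[gate] and (changed or slope_ratio > ratio_threshold):
        label = "repression_anomaly" if direction == "repression" else "induction_anomaly"
    else:
        label = "unchanged"
    return TrendCall(gene_id, direction, mk_wt, mk_ko, float(slope_ratio), label)


def summarize_classification(calls: list[TrendCall]) -> pd.DataFrame:
    """Count and percentage per anomaly label (percentages to 1 decimal)."""
    counts = {label: 0 for label in LABELS}
    for call in calls:
        counts[call.label] += 1
    total = sum(counts.values())
    rows = [
        {
            "label": label,
            "count": c,
            "percent": round(100.0 * c / total, 1) if total else 0.0,
        }
        for label, c in counts.items()
    ]
    rows.append({"label": "total", "count": total, "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[TrendCall]) -> pd.DataFrame:
    """Flat per-gene table of trend statistics for export."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "direction": c.direction,
                "S_wt": c.mk_wt.S,
                "p_wt": c.mk_wt.p,
                "slope_wt": c.mk_wt.slope,
                "S_ko": c.mk_ko.S,
                "p_ko": c.mk_ko.p,
                "slope_ko": c.mk_ko.slope,
                "slope_ratio": c.slope_ratio,
                "label": c.label,
                "audit_flag": c.audit_flag,
            }
        )
    return pd.DataFrame(rows)
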