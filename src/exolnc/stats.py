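"""Shared statistics: tie-corrected Kendall tau-b, one-way ANOVA on
transcript lengths, and normal-cutoff confidence.

Kendall tau-b is the appropriate rank correlation for the length
diagnostics because motif counts per transcript are heavily tied and
far from normal.  Strength labels use a 0.3/0.6/0.8 banding:
|tau| < 0.3 'negligible', 0.3-0.6 'weak', 0.6-0.8 'moderate',
>= 0.8 'strong'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

STRENGTH_BANDS = [(0.3, "negligible"), (0.6, "weak"), (0.8, "moderate")]


def strength_label(coefficient: float) -> str:
    a = abs(coefficient)
    for bound, label in STRENGTH_BANDS:
        if a < bound:
            return label
    return "strong"


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str

    @property
    def strength(self) -> str:
        return strength_label(self.coefficient)


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall's tau-b with tie correction and two-sided p-value.

    tau-b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with C/D the concordant/
    discordant pair counts, n0 = n(n-1)/2 and n1/n2 the within-tie pair
    counts of x and y.  p uses the normal approximation with
    tie-corrected variance for n > 10 and exact enumeration otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined for an all-tied vector")
    has_ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    # scipy's exact null enumeration assumes no ties
    method = "exact" if (len(x) <= 10 and not has_ties) else "asymptotic"
    tau, p = sps.kendalltau(x, y, variant="b", method=method)
    return CorrelationResult(float(tau), float(p), len(x), "kendall-tau-b")


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: list[float]
    mean_difference: float  # max mean minus min mean


def anova_lengths(*groups: Sequence[float]) -> AnovaResult:
    """One-way ANOVA across two or more groups of transcript lengths."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    f, p = sps.f_oneway(*arrays)
    means = [float(a.mean()) for a in arrays]
    return AnovaResult(float(f), float(p), means, max(means) - min(means))


def normal_confidence(z: float) -> float:
    """One-sided coverage probability Phi(z) of a z-score cutoff.

    A cutoff of 3 gives 0.99865, i.e. ~0.999: a value at z >= 3 lies in
    the extreme 0.1% tail of its distribution.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(sps.norm.cdf(z))
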