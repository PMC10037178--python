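"""Between-group and correlation statistics, from definitional formulas.

The four procedures used by the cohort analysis — one-way ANOVA,
Tukey-Kramer post hoc comparisons, Spearman rank correlation and the
one-sample t-test — are implemented directly from their sums-of-squares /
rank definitions so each can be verified against an independent reference
implementation in the test suite.  Only the reference distributions
(F, Student t, studentized range) come from :mod:`scipy.stats`.

No family-wise multiple-comparison correction is applied anywhere; the
pipeline records this choice explicitly in its run manifest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy import stats as sps


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float] = field(default_factory=dict)
    group_ns: dict[str, int] = field(default_factory=dict)


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    diff: float          # mean(a) - mean(b)
    se: float            # Tukey-Kramer standard error
    q: float             # studentized-range statistic
    p_adj: float


@dataclass
class TukeyResult:
    pairs: list[TukeyPair]
    df_within: int
    alpha: float

    def pair(self, a: str, b: str) -> TukeyPair:
        for pr in self.pairs:
            if {pr.group_a, pr.group_b} == {a, b}:
                return pr
        raise KeyError((a, b))


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    n_dropped: int = 0


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        items = groups.items()
    else:
        items = ((f"group{i}", g) for i, g in enumerate(groups))
    out = {}
    for name, g in items:
        arr = np.asarray(g, dtype=float)
        arr = arr[np.isfinite(arr)]
        out[str(name)] = arr
    return out


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA.

    ``F = MS_between / MS_within`` with ``SS_between = sum n_i (m_i - m)^2``
    and ``SS_within = sum_i sum_j (x_ij - m_i)^2``; the p-value comes from
    the F distribution on (k-1, N-k) degrees of freedom.

    ``groups`` is a mapping name -> values or a sequence of value arrays;
    non-finite entries are dropped (listwise within each group).
    """
    gdict = _as_groups(groups)
    if len(gdict) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for name, g in gdict.items():
        if len(g) < 2:
            raise ValueError(f"ANOVA group {name!r} has fewer than 2 values")
    k = len(gdict)
    ns = {name: len(g) for name, g in gdict.items()}
    means = {name: float(np.mean(g)) for name, g in gdict.items()}
    n_total = sum(ns.values())
    grand = sum(ns[name] * means[name] for name in gdict) / n_total
    ssb = sum(ns[name] * (means[name] - grand) ** 2 for name in gdict)
    ssw = sum(float(np.sum((g - means[name]) ** 2)) for name, g in gdict.items())
    dfb, dfw = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            F, p = 0.0, 1.0
        else:
            warnings.warn("zero within-group variance everywhere; F is infinite")
            F, p = math.inf, 0.0
    else:
        F = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(F=float(F), df_between=dfb, df_within=dfw, p=p,
                       group_means=means, group_ns=ns)


def tukey_hsd(groups, alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey honestly-significant-difference test.

    Uses the Tukey-Kramer standard error for unequal group sizes,
    ``SE_ij = sqrt(MS_within/2 * (1/n_i + 1/n_j))``, with
    ``q_ij = |m_i - m_j| / SE_ij`` referred to the studentized-range
    distribution with ``k`` groups and ``N - k`` degrees of freedom.
    """
    gdict = _as_groups(groups)
    if len(gdict) < 2:
        raise ValueError("Tukey test needs at least 2 groups")
    for name, g in gdict.items():
        if len(g) < 2:
            raise ValueError(f"Tukey group {name!r} has fewer than 2 values")
    k = len(gdict)
    n_total = sum(len(g) for g in gdict.values())
    dfw = n_total - k
    ssw = sum(float(np.sum((g - np.mean(g)) ** 2)) for g in gdict.values())
    msw = ssw / dfw
    pairs: list[TukeyPair] = []
    for a, b in combinations(gdict, 2):
        ga, gb = gdict[a], gdict[b]
        diff = float(np.mean(ga) - np.mean(gb))
        se = math.sqrt(msw / 2.0 * (1.0 / len(ga) + 1.0 / len(gb)))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            if q:
                warnings.warn("zero pooled variance with nonzero difference")
            p = 1.0 if q == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, dfw))
        pairs.append(TukeyPair(a, b, diff, se, q, min(max(p, 0.0), 1.0)))
    return TukeyResult(pairs=pairs, df_within=dfw, alpha=alpha)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    ``rho`` is the Pearson correlation of the rank vectors; the p-value uses
    the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` on ``n-2``
    degrees of freedom.  Pairs with a missing member are dropped pairwise
    and counted in ``n_dropped``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined")
        return CorrelationResult(rho=math.nan, p=math.nan, n=n, n_dropped=n_dropped)
    rx = sps.rankdata(x)  # mid-ranks for ties
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p=p, n=n, n_dropped=n_dropped)


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float, int]:
    """Two-sided one-sample t-test of ``mean(values) == mu0``.

    Returns ``(t, p, df)`` with ``t = (mean - mu0) / (SD / sqrt(n))`` and
    ``df = n - 1``.  A zero-variance sample gives ``t = 0, p = 1`` when the
    mean equals ``mu0`` and an infinite t (with a warning) otherwise.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < 2:
        raise ValueError("one-sample t-test needs at least 2 finite values")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == mu0:
            return 0.0, 1.0, df
        warnings.warn("zero variance with mean != mu0; t is infinite")
        return math.copysign(math.inf, mean - mu0), 0.0, df
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), p, df
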