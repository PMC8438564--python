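"""Independent brute-force reference implementations used only by the tests.

Each function recomputes a statistic by direct enumeration or a literal
step-by-step transcription of its definition, deliberately sharing no code
with the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def naive_ssgsea(expr_col: pd.Series, genes, alpha: float) -> float:
    """Literal running-sum: walk genes in descending rank order, accumulating
    the weighted in-set ECDF minus the uniform out-of-set ECDF.

    Exact for tie-free columns (ties here are walked in symbol order, whereas
    the engine averages over tie orders), so fixtures using this oracle for
    strict equality draw continuous values.
    """
    ranks = expr_col.rank(method="average")
    order = sorted(ranks.index, key=lambda g: (-ranks[g], g))
    member = set(genes) & set(order)
    G, k = len(order), len(member)
    assert 0 < k < G
    w_total = sum(ranks[g] ** alpha for g in member)
    score = p_in = p_out = 0.0
    for g in order:
        if g in member:
            p_in += ranks[g] ** alpha / w_total
        else:
            p_out += 1.0 / (G - k)
        score += p_in - p_out
    return score


def bh_reference(pvals) -> np.ndarray:
    """Textbook Benjamini–Hochberg step-up q-values via explicit loops."""
    p = list(map(float, pvals))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        q[i] = running_min
    return np.asarray(q)


def mannwhitney_exact_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Uses the symmetric-extremity definition P(|U - n1*n2/2| >= |u_obs - ...|)
    over the permutation distribution of the U statistic with tie-adjusted
    midranks.
    """
    x, y = list(x), list(y)
    combined = x + y
    n1, n2 = len(x), len(y)
    ranks = pd.Series(combined).rank(method="average").to_numpy()

    def u_stat(indices) -> float:
        r1 = sum(ranks[i] for i in indices)
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_stat(range(n1))
    center = n1 * n2 / 2
    dev = abs(u_obs - center)
    total = more_extreme = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_stat(combo) - center) >= dev - 1e-12:
            more_extreme += 1
    return more_extreme / total


def cindex_bruteforce(risk, times, events) -> float:
    """Pairwise loop transcription of Harrell's C definition."""
    n = len(risk)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den if den else 0.5


def logrank_tally(times, events, groups):
    """(O - E, V) for group 0 via the standard per-event-time 2x2 tally."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    group0 = np.sort(np.unique(groups))[0]
    o_minus_e = v = 0.0
    for tt in sorted(set(times[events == 1])):
        at_risk = times >= tt
        n = at_risk.sum()
        n0 = (at_risk & (groups == group0)).sum()
        d = ((times == tt) & (events == 1)).sum()
        d0 = ((times == tt) & (events == 1) & (groups == group0)).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            v += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o_minus_e, v


def welch_t(x, y):
    """Closed-form Welch t statistic and Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    tstat = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return tstat, df
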