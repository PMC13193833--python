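"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths (and, where feasible, the
libraries) they are checking: the Fisher oracle enumerates hypergeometric
tables with exact integer combinatorics, the BH oracle is the textbook
sorted cumulative-minimum, and the log-rank oracle is the explicit
observed-minus-expected sum over distinct event times.
"""

from math import comb

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int, tol: float = 1e-12) -> float:
    """Two-sided Fisher p by full enumeration of tables with the observed
    margins: sum of probabilities of all tables at most as probable."""
    n = a + b + c + d
    row = a + b
    col = a + c
    denom = comb(n, col)

    def pk(k: int) -> float:
        return comb(row, k) * comb(n - row, col - k) / denom

    p_obs = pk(a)
    lo, hi = max(0, row + col - n), min(row, col)
    return float(sum(pk(k) for k in range(lo, hi + 1) if pk(k) <= p_obs * (1 + tol)))


def bh_stepup(p):
    """Benjamini-Hochberg adjusted values: sort, scale by m/rank, take the
    cumulative minimum from the largest rank down, clip at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


def logrank_two_group(times1, events1, times2, events2) -> float:
    """Two-group log-rank chi-squared, (O1-E1)^2 / V, by explicit iteration
    over the distinct event times with the hypergeometric variance."""
    t1, e1 = np.asarray(times1, float), np.asarray(events1, int)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, int)
    all_times = np.concatenate([t1, t2])
    all_events = np.concatenate([e1, e2])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(all_times[all_events == 1]):
        n1 = int((t1 >= t).sum())
        n2 = int((t2 >= t).sum())
        n = n1 + n2
        d = int(((all_times == t) & (all_events == 1)).sum())
        d1 = int(((t1 == t) & (e1 == 1)).sum())
        if n == 0:
            continue
        e = d * n1 / n
        o_minus_e += d1 - e
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0
    return o_minus_e**2 / var


def km_no_censoring_survival(times):
    """1 - ECDF evaluated at each distinct time (all-events case)."""
    times = np.sort(np.asarray(times, float))
    uniq = np.unique(times)
    n = len(times)
    return uniq, np.array([(times > t).sum() / n for t in uniq])
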