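"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition with plain
loops over risk tables and subject pairs, sharing no code with the package
implementations they check.
"""

import math

import numpy as np


def logrank_bruteforce(times, events, membership):
    """Standardized two-group log-rank via an explicit per-event-time
    risk table: O - E in group 1 over sqrt of the hypergeometric variance."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    memb = np.asarray(membership).astype(bool)
    observed = expected = variance = 0.0
    for u in sorted(set(times[events == 1])):
        at_risk = times >= u
        Y = int(at_risk.sum())
        Y1 = int((at_risk & memb).sum())
        d = int(((times == u) & (events == 1)).sum())
        d1 = int(((times == u) & (events == 1) & memb).sum())
        observed += d1
        expected += d * Y1 / Y
        if Y > 1:
            variance += d * (Y1 / Y) * (1 - Y1 / Y) * (Y - d) / (Y - 1)
    if variance <= 0:
        return math.nan
    return (observed - expected) / math.sqrt(variance)


def cindex_bruteforce(times, events, risks):
    """Harrell's C by exhaustive ordered-pair enumeration.

    Pair (i, j) is permissible when t_i < t_j and subject i is an event,
    or t_i == t_j with i an event and j censored.  Tied-time pairs with
    both events are excluded.  Score: 1 if r_i > r_j, 0.5 on a risk tie,
    else 0.
    """
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            perm = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not perm:
                continue
            den += 1
            if risks[i] > risks[j]:
                num += 1
            elif risks[i] == risks[j]:
                num += 0.5
    if den == 0:
        return math.nan
    return num / den


def nelson_aalen_bruteforce(times, events, t):
    """CHF at a single time t from an explicit risk table."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    total = 0.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        d = int(((times == u) & (events == 1)).sum())
        Y = int((times >= u).sum())
        total += d / Y
    return total


def best_split_bruteforce(times, events, X, min_node_size):
    """Exhaustive (variable, threshold) scan maximizing |log-rank|."""
    best = None
    best_val = -math.inf
    n, p = X.shape
    for v in range(p):
        vals = sorted(set(X[:, v]))
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (a + b)
            memb = X[:, v] <= thr
            n_left = int(memb.sum())
            if n_left < min_node_size or n - n_left < min_node_size:
                continue
            stat = logrank_bruteforce(times, events, memb)
            if math.isnan(stat):
                continue
            if abs(stat) > best_val + 1e-12:
                best_val = abs(stat)
                best = (v, thr)
    return best
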