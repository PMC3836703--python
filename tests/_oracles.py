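"""Independent brute-force oracles used to check the fast implementations.

Everything here is written from the textbook definitions with plain
Python loops and is deliberately independent of the package's code
paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps


def brute_pearson(x, y):
    """Pearson r and two-sided t-transform p by the direct formulas."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    r = cov / math.sqrt(vx * vy)
    if abs(r) >= 1:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * sps.t.sf(abs(t), n - 2)


def brute_logrank_chi2(times, events, labels):
    """Two-group log-rank chi-square by explicit accumulation of O, E, V."""
    data = sorted(zip(times, events, labels))
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({t for t, e, _ in data if e}):
        at_risk = [(e, g) for tt, e, g in data if tt >= t]
        n_j = len(at_risk)
        n1_j = sum(1 for _, g in at_risk if g)
        d_j = sum(1 for tt, e, _ in data if tt == t and e)
        d1_j = sum(1 for tt, e, g in data if tt == t and e and g)
        o_minus_e += d1_j - d_j * n1_j / n_j
        if n_j > 1:
            var += (
                d_j
                * (n1_j / n_j)
                * (1 - n1_j / n_j)
                * (n_j - d_j)
                / (n_j - 1)
            )
    if var <= 0:
        return 0.0
    return o_minus_e**2 / var


def exact_ranksum_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Tie-free samples only. Follows the doubled one-sided convention
    (2 * min(P(U <= u), P(U >= u)), capped at 1).
    """
    pooled = list(a) + list(b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), na):
        grp = set(comb)
        aa = [pooled[i] for i in comb]
        bb = [pooled[i] for i in range(len(pooled)) if i not in grp]
        us.append(sum(1 for x in aa for y in bb if x > y))
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(p_le, p_ge))


def km_hand_table(subjects):
    """Product-limit estimate from (time, event) pairs by the definition."""
    out_t, out_s, out_n = [], [], []
    s = 1.0
    for t in sorted({t for t, e in subjects if e}):
        n_j = sum(1 for tt, _ in subjects if tt >= t)
        d_j = sum(1 for tt, e in subjects if tt == t and e)
        s *= 1 - d_j / n_j
        out_t.append(t)
        out_s.append(s)
        out_n.append(n_j)
    return out_t, out_s, out_n


def max_abs_r_over_subsets(x, y, triple):
    """Max |Pearson r| over every subset that contains the seed triple."""
    n = len(x)
    rest = [i for i in range(n) if i not in triple]
    best = 0.0
    for k in range(len(rest) + 1):
        for extra in itertools.combinations(rest, k):
            idx = list(triple) + list(extra)
            xs = np.asarray(x)[idx]
            ys = np.asarray(y)[idx]
            if xs.std() == 0 or ys.std() == 0:
                continue
            r = abs(np.corrcoef(xs, ys)[0, 1])
            best = max(best, r)
    return best
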