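"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the defining formulas, with plain
loops and no reuse of package internals, so agreement with the package is
a genuine cross-check.
"""

import numpy as np


def naive_efron_loglik(beta, x, time, event):
    """Efron log partial likelihood for one covariate, by direct tabulation."""
    eta = beta * np.asarray(x, float)
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.nonzero((time == t) & (event == 1))[0]
        R = np.nonzero(time >= t)[0]
        d = len(D)
        s_r = w[R].sum()
        s_d = w[D].sum()
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(s_r - (l / d) * s_d)
    return ll


def grid_max_efron(x, time, event, lo=-3.0, hi=3.0, coarse=1e-3, fine=1e-5):
    """Maximize the 1-D Efron partial likelihood by grid search (step 1e-5)."""
    grid = np.arange(lo, hi + coarse, coarse)
    vals = [naive_efron_loglik(b, x, time, event) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    grid = np.arange(b0 - 2 * coarse, b0 + 2 * coarse + fine, fine)
    vals = [naive_efron_loglik(b, x, time, event) for b in grid]
    return float(grid[int(np.argmax(vals))])


def stepup_bh(p):
    """Benjamini-Hochberg step-up by the literal definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return q


def brute_logrank_chi2(time, event, group):
    """Two-group log-rank chi-square by direct O/E/V tabulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g = np.asarray(group)
    labels = np.unique(g)
    o_e, v = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (g == labels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (g == labels[0])).sum()
        o_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    return o_e**2 / v


def mann_whitney_auc(scores, labels):
    """Plain rank-sum AUC of a binary status, ties counted one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


def naive_km(time, event):
    """Product-limit survival curve by direct evaluation."""
    times = sorted(set(np.asarray(time)[np.asarray(event) == 1]))
    s = 1.0
    out = []
    for t in times:
        n = (np.asarray(time) >= t).sum()
        d = ((np.asarray(time) == t) & (np.asarray(event) == 1)).sum()
        s *= 1 - d / n
        out.append((t, s))
    return out
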