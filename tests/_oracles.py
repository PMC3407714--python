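"""Independent brute-force oracles used by the unit and acceptance tests.

Each function here is deliberately written against the *definition* of
the statistic (enumeration, hand product-limit arithmetic, grid search),
not against the package implementation it checks.
"""

import numpy as np


def breslow_loglik(beta, X, time, event):
    """Breslow partial log-likelihood by direct risk-set enumeration."""
    beta = np.asarray(beta, dtype=float)
    lp = X @ beta
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += lp[i] - np.log(np.sum(np.exp(lp[risk])))
    return ll


def grid_search_cox(X, time, event, lo=-3.0, hi=3.0, rounds=4, n_grid=41):
    """Maximize the Breslow partial likelihood by iterative dense grids."""
    p = X.shape[1]
    centers = np.zeros(p)
    half = (hi - lo) / 2.0
    best = centers
    for _ in range(rounds):
        axes = [np.linspace(c - half, c + half, n_grid) for c in centers]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.column_stack([g.ravel() for g in grids])
        lls = np.array([breslow_loglik(b, X, time, event) for b in flat])
        best = flat[int(np.argmax(lls))]
        centers = best
        half = half * 2.0 / (n_grid - 1) * 1.5  # bracket around the best point
    return best


def hand_logrank(time, event, group):
    """Two-group log-rank chi-square from observed-minus-expected sums."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == labels[1])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == labels[1])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def brute_auc(scores, labels):
    """AUC as the concordant-pair fraction over all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_passing_bablok_slope(x, y):
    """Shifted median of pairwise slopes with the offset correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slopes = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] == x[i]:
                if y[j] != y[i]:
                    slopes.append(np.inf if y[j] > y[i] else -np.inf)
                continue
            s = (y[j] - y[i]) / (x[j] - x[i])
            if s != -1.0:
                slopes.append(s)
    slopes = sorted(slopes)
    N = len(slopes)
    K = sum(1 for s in slopes if s < -1.0)
    if N % 2 == 1:
        return slopes[min((N + 1) // 2 + K, N) - 1]
    a = slopes[min(N // 2 + K, N) - 1]
    b = slopes[min(N // 2 + 1 + K, N) - 1]
    return 0.5 * (a + b)


def km_by_hand(time, event):
    """Product-limit curve as a list of (event_time, survival) pairs."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    s = 1.0
    out = []
    for t in np.unique(time[event == 1]):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1.0 - d / n
        out.append((t, s))
    return out
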