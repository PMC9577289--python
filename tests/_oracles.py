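"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each statistic from first principles with
naive loops so they share no code path with the package implementation.
"""

import numpy as np


def brute_force_ward(points: np.ndarray, squared: bool) -> list[float]:
    """Naive Lance–Williams Ward agglomeration; returns sorted merge heights.

    Maintains explicit cluster membership lists and a dense dissimilarity
    dictionary, applying the Ward update term by term.
    """
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.linalg.norm(points[i] - points[j]))
            d[(i, j)] = dist ** 2 if squared else dist
    heights = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(h) if squared else h)
        ni, nj = len(clusters[i]), len(clusters[j])
        new = {}
        for (a, b), dab in d.items():
            if i in (a, b) and j in (a, b):
                continue
            if i in (a, b) or j in (a, b):
                continue
            new[(a, b)] = dab
        for k in clusters:
            if k in (i, j):
                continue
            nk = len(clusters[k])
            dki = d[tuple(sorted((k, i)))]
            dkj = d[tuple(sorted((k, j)))]
            dij = d[tuple(sorted((i, j)))]
            val = ((ni + nk) * dki + (nj + nk) * dkj - nk * dij) / (ni + nj + nk)
            new[tuple(sorted((k, next_id)))] = val
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        d = new
        next_id += 1
    return sorted(heights)


def brute_force_logrank(times, events, groups) -> float:
    """Two-group log-rank chi-square by per-event-time hypergeometric sums."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e ** 2 / var)


def efron_partial_loglik(beta: float, times, events, x) -> float:
    """Efron-tie Cox partial log-likelihood for a single covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    eta = beta * x
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events]):
        dead = events & (times == t)
        risk = times >= t
        d = int(dead.sum())
        sum_risk = theta[risk].sum()
        sum_dead = theta[dead].sum()
        ll += eta[dead].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_dead)
    return float(ll)


def golden_section_max(f, lo: float, hi: float, tol: float = 1e-8) -> float:
    """Golden-section maximizer of a unimodal scalar function."""
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    while abs(b - a) > tol:
        if f(c) > f(d):
            b = d
        else:
            a = c
        c = b - phi * (b - a)
        d = a + phi * (b - a)
    return (a + b) / 2
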