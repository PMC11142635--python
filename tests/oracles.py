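"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, O(n^2)
loops) and shares no code with the package internals it checks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def exact_final_state_distribution(weights, seed_set, gamma):
    """Exact absorbing-state distribution of the synchronous SIR chain.

    State: per-node 0 (susceptible) / 1 (ictal) / 2 (recovered). One step:
    every susceptible j becomes ictal with probability
    1 - prod_{i ictal}(1 - w_ij) (independently), then every node that was
    ictal at the start of the step recovers with probability gamma. The
    per-node stage sum strictly increases on any change, so transient
    states form a DAG (self-loops resummed geometrically) and exact
    absorption probabilities follow by topological-order propagation.

    Returns dict: tuple of final codes (0/2 per node) -> probability.
    """
    n = len(weights)
    w = np.asarray(weights, dtype=float)
    start = tuple(1 if i in set(seed_set) else 0 for i in range(n))

    def successors(state):
        ictal = [i for i in range(n) if state[i] == 1]
        sus = [i for i in range(n) if state[i] == 0]
        p_inf = {j: 1.0 - np.prod([1.0 - w[i][j] for i in ictal]) for j in sus}
        out = {}
        for newly in _subsets(sus):
            p1 = 1.0
            for j in sus:
                p1 *= p_inf[j] if j in newly else 1.0 - p_inf[j]
            if p1 == 0.0:
                continue
            for recovered in _subsets(ictal):
                p2 = gamma ** len(recovered) * (1.0 - gamma) ** (len(ictal) - len(recovered))
                if p2 == 0.0:
                    continue
                nxt = list(state)
                for j in newly:
                    nxt[j] = 1
                for i in recovered:
                    nxt[i] = 2
                nxt = tuple(nxt)
                out[nxt] = out.get(nxt, 0.0) + p1 * p2
        return out

    # propagate probability mass in order of increasing stage sum
    pending = {start: 1.0}
    absorbed = {}
    while pending:
        state = min(pending, key=sum)
        mass = pending.pop(state)
        if 1 not in state:
            absorbed[state] = absorbed.get(state, 0.0) + mass
            continue
        succ = successors(state)
        p_stay = succ.pop(state, 0.0)
        scale = mass / (1.0 - p_stay)
        for nxt, p in succ.items():
            pending[nxt] = pending.get(nxt, 0.0) + scale * p
    return absorbed


def _subsets(items):
    for r in range(len(items) + 1):
        yield from (set(c) for c in combinations(items, r))


def floyd_warshall(lengths):
    """Plain O(n^3) all-pairs shortest paths; 0 entries mean no edge."""
    n = len(lengths)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and lengths[i][j] > 0:
                d[i, j] = lengths[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def pairwise_auc(scores, labels, positive="NSF"):
    """AUC as the fraction of correctly ordered (negative, positive) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def weighted_pearson_bruteforce(x, y, w):
    """Direct evaluation of the weighted-moment formula."""
    sw = sum(w)
    mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
    my = sum(wi * yi for wi, yi in zip(w, y)) / sw
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y)) / sw
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x)) / sw
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y)) / sw
    return cov / (vx * vy) ** 0.5


def brute_force_min_energy(energy, n, size):
    """Exhaustive minimum of a set-function energy over all C(n, size) subsets."""
    best, best_set = np.inf, None
    for subset in combinations(range(n), size):
        e = energy(np.asarray(subset, dtype=int))
        if e < best:
            best, best_set = e, subset
    return best, best_set


def ranksum_pvalue_bruteforce(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    from scipy.stats import rankdata

    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), nx)]
    sums = np.asarray(sums)
    p_low = np.mean(sums <= obs + 1e-12)
    p_high = np.mean(sums >= obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))
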