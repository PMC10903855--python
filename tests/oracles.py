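"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations (explicit loops, direct formulas) kept
free of any code path shared with the package.
"""

import numpy as np


def gini(labels) -> float:
    labels = np.asarray(labels)
    n = len(labels)
    return 1.0 - sum((np.sum(labels == c) / n) ** 2 for c in set(labels.tolist()))


def node_impurity(target, criterion: str) -> float:
    target = np.asarray(target, dtype=float)
    if criterion == "gini":
        return gini(target)
    return float(np.var(target))


def brute_force_best_split(X, target, criterion, min_bucket=1):
    """Exhaustive search over every (covariate, midpoint cut) pair.

    Returns (gain, feature, threshold, unique) where ``unique`` is True
    when the optimum exceeds every other admissible cut by > 1e-9, or None
    when no admissible cut improves on the parent impurity.
    """
    X = np.asarray(X, dtype=float)
    target = np.asarray(target)
    n, p = X.shape
    parent = node_impurity(target, criterion)
    gains = []
    for j in range(p):
        values = np.unique(X[:, j])
        for a, b in zip(values[:-1], values[1:]):
            thr = 0.5 * (a + b)
            if thr >= b:
                thr = a
            left = X[:, j] <= thr
            nl = int(left.sum())
            nr = n - nl
            if nl < min_bucket or nr < min_bucket:
                continue
            child = (
                nl * node_impurity(target[left], criterion)
                + nr * node_impurity(target[~left], criterion)
            ) / n
            gains.append((parent - child, j, float(thr)))
    if not gains:
        return None
    best = max(gains, key=lambda g: (g[0], -g[1], -g[2]))
    if best[0] <= 1e-12:
        return None
    runners = [g[0] for g in gains if (g[1], g[2]) != (best[1], best[2])]
    unique = all(best[0] - g > 1e-9 for g in runners)
    # tie-break exactly as documented: highest gain, lowest feature, lowest cut
    ties = [g for g in gains if abs(g[0] - best[0]) <= 1e-12]
    winner = min(ties, key=lambda g: (g[1], g[2]))
    return winner[0], winner[1], winner[2], unique
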