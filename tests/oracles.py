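"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths (and vectorised
numpy where feasible): plain loops over pixels and plain arithmetic, so
they can act as ground truth for the optimised implementations.
"""

from __future__ import annotations

import math


def confusion_loop(y, y_hat):
    """Pixel-by-pixel confusion counts via an explicit Python loop."""
    tp = fp = tn = fn = 0
    rows, cols = y.shape
    for r in range(rows):
        for c in range(cols):
            t, p = int(y[r, c]), int(y_hat[r, c])
            if t and p:
                tp += 1
            elif t and not p:
                fn += 1
            elif not t and p:
                fp += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def dice_from_counts(tp, fp, fn):
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def iou_from_counts(tp, fp, fn):
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def staple_em_loop(decisions, gamma, p0, q0, n_iter, eps=1e-6):
    """Plain-arithmetic binary STAPLE EM on a small instance.

    ``decisions`` is an R x N list of 0/1 lists.  Runs exactly ``n_iter``
    E/M sweeps (no convergence shortcut) and returns (p, q, W) where W is
    evaluated with the final parameters.
    """
    r = len(decisions)
    n = len(decisions[0])
    p = [p0] * r
    q = [q0] * r

    def e_step():
        w = []
        for i in range(n):
            a = gamma
            b = 1.0 - gamma
            for j in range(r):
                d = decisions[j][i]
                a *= p[j] if d else (1.0 - p[j])
                b *= (1.0 - q[j]) if d else q[j]
            w.append(a / (a + b))
        return w

    for _ in range(n_iter):
        w = e_step()
        wsum = sum(w)
        notwsum = sum(1.0 - wi for wi in w)
        for j in range(r):
            num_p = sum(w[i] for i in range(n) if decisions[j][i])
            num_q = sum((1.0 - w[i]) for i in range(n) if not decisions[j][i])
            p[j] = min(max(num_p / wsum, eps), 1.0 - eps)
            q[j] = min(max(num_q / notwsum, eps), 1.0 - eps)
    return p, q, e_step()


def wilcoxon_exact_all_positive(n):
    """Exact two-sided signed-rank p for n all-positive differences with
    distinct magnitudes, by enumerating all 2^n sign assignments."""
    ranks = list(range(1, n + 1))
    total = sum(ranks)
    observed = total  # all positive -> W+ = sum of all ranks
    stat = min(observed, total - observed)
    count = 0
    for signs in range(2 ** n):
        w_plus = sum(ranks[i] for i in range(n) if (signs >> i) & 1)
        if min(w_plus, total - w_plus) <= stat:
            count += 1
    return count / 2 ** n


def hochberg_stepup(pvals):
    """Direct transcription of the Hochberg step-up adjustment."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    prev = math.inf
    for k in reversed(range(m)):
        i = order[k]
        prev = min(prev, (m - k) * pvals[i])
        adj[i] = min(prev, 1.0)
    return adj
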