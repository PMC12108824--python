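"""Independent reference implementations used only as test oracles.

Deliberately naive (explicit loops, no pruning, no shared code with the
package) so that agreement with the optimized implementations is evidence
of correctness rather than of shared bugs.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_segment(x, penalty: float, min_seg_len: int = 1):
    """Unpruned O(n^2) optimal-partition DP with L2 segment cost.

    Returns (sorted change points, total cost = sum of segment costs +
    penalty * number_of_change_points).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)

    def seg_cost(a, b):
        seg = x[a:b]
        return float(((seg - seg.mean()) ** 2).sum())

    F = [math.inf] * (n + 1)
    F[0] = -penalty
    prev = [0] * (n + 1)
    for t in range(1, n + 1):
        for s in range(0, t - min_seg_len + 1):
            v = F[s] + seg_cost(s, t) + penalty
            if v < F[t]:
                F[t] = v
                prev[t] = s
    cps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps), F[n]


def enumerate_partitions_best(x, penalty: float):
    """Exhaustive search over all 2^(n-1) boundary subsets (tiny n only)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (math.inf, [])
    for mask in range(2 ** (n - 1)):
        bounds = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
        cost = sum(
            float(((x[a:b] - x[a:b].mean()) ** 2).sum())
            for a, b in zip(bounds[:-1], bounds[1:])
        ) + penalty * (len(bounds) - 2)
        if cost < best[0]:
            best = (cost, bounds[1:-1])
    return best[1], best[0]


def naive_sliding_std_flux(H, w: int):
    """Trailing-window population-std sum, recomputed per window."""
    H = np.asarray(H, dtype=float)
    n, k = H.shape
    out = []
    for i in range(n):
        lo = max(0, i - w + 1)
        total = 0.0
        for j in range(k):
            seg = H[lo : i + 1, j]
            mu = sum(seg) / len(seg)
            total += math.sqrt(sum((v - mu) ** 2 for v in seg) / len(seg))
        out.append(total)
    return np.array(out)


def naive_bocpd_posterior(x, hazard, mu0, kappa0, alpha0, beta0):
    """Plain-loop run-length posterior (Normal obs., NIG prior).

    Returns the list of posterior vectors P(r_t | x_1..t), one per step.
    """

    def t_pdf(y, df, loc, scale):
        z = (y - loc) / scale
        lognorm = (
            math.lgamma((df + 1) / 2)
            - math.lgamma(df / 2)
            - 0.5 * math.log(df * math.pi)
            - math.log(scale)
        )
        return math.exp(lognorm - (df + 1) / 2 * math.log(1 + z * z / df))

    params = [(mu0, kappa0, alpha0, beta0)]
    probs = [1.0]
    out = []
    for y in x:
        pred = [
            t_pdf(y, 2 * a, m, math.sqrt(b * (k + 1) / (a * k)))
            for (m, k, a, b) in params
        ]
        growth = [p * q * (1 - hazard) for p, q in zip(probs, pred)]
        cp = sum(p * q * hazard for p, q in zip(probs, pred))
        new = [cp] + growth
        z = sum(new)
        probs = [v / z for v in new]
        new_params = [(mu0, kappa0, alpha0, beta0)]
        for (m, k, a, b) in params:
            new_params.append(
                (
                    (k * m + y) / (k + 1),
                    k + 1,
                    a + 0.5,
                    b + k * (y - m) ** 2 / (2 * (k + 1)),
                )
            )
        params = new_params
        out.append(np.array(probs))
    return out
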