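"""Independent brute-force oracles used to check the package's closed-form
or library-backed computations.  These deliberately avoid the code paths
they verify."""

import numpy as np


def dss1_trapezoid(b, c, d, e, x_min, x_max, t, n=10_001):
    """Numeric variant-1 DSS by dense trapezoid integration in log10 dose."""
    u = np.linspace(x_min, x_max, n)
    x = 10.0 ** u
    inh = c + (d - c) / (1.0 + (e / x) ** b)
    area = np.trapezoid(np.clip(inh - t, 0.0, None), u)
    return 100.0 * area / ((100.0 - t) * (x_max - x_min))


def holm_stepdown(pvalues):
    """Textbook Holm step-down adjustment, one comparison at a time."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def ward_d2_linkage(points):
    """Exhaustive Ward-d2 agglomeration of observation rows.

    Returns the merge heights in order, where the distance between clusters
    A, B is sqrt(2 nA nB / (nA + nB)) * ||centroid_A - centroid_B||, the
    Ward criterion scaled as in standard linkage output.
    """
    clusters = [(1, np.asarray(p, dtype=float)) for p in points]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                na, ca = clusters[i]
                nb, cb = clusters[j]
                dist = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        na, ca = clusters[i]
        nb, cb = clusters[j]
        merged = (na + nb, (na * ca + nb * cb) / (na + nb))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        heights.append(dist)
    return np.array(heights)


def ic_p_bisect(b, c, d, e, p, lo=1e-18, hi=1e6, iters=200):
    """Root-find the dose at p% inhibition without using the closed form."""
    def inh(x):
        return c + (d - c) / (1.0 + (e / x) ** b)

    f_lo, f_hi = inh(lo) - p, inh(hi) - p
    if f_lo * f_hi > 0:
        raise ValueError("p not bracketed")
    for _ in range(iters):
        mid = np.sqrt(lo * hi)
        if (inh(mid) - p) * f_lo <= 0:
            hi = mid
        else:
            lo = mid
    return np.sqrt(lo * hi)
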