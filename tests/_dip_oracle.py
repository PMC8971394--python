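"""LP-feasibility oracle for the dip statistic (small n)."""
import numpy as np
from scipy.optimize import linprog


def _feasible(u, cum, n, d, t):
    # variables: G_0..G_{m-1}, L  (mode at u[t], jump from L to G_t allowed)
    m = len(u)
    nv = m + 1
    L = m  # index of L variable
    A, b = [], []

    def ub(coefs, rhs):  # sum coefs*x <= rhs
        row = np.zeros(nv); 
        for i, c in coefs: row[i] += c
        A.append(row); b.append(rhs)

    left = lambda j: (cum[j-1] if j > 0 else 0) / n
    right = lambda j: cum[j] / n
    for j in range(m):
        ub([(j, -1.0)], -(right(j) - d))          # G_j >= F_j - d
        if j != t:
            ub([(j, 1.0)], left(j) + d)           # G_j <= F_j^- + d
        else:
            ub([(j, 1.0)], right(j) + d)          # relaxed at the mode
    ub([(L, -1.0)], -(left(t) - d))
    ub([(L, 1.0)], left(t) + d)
    # monotone
    for j in range(m - 1):
        if j + 1 == t:
            ub([(j, 1.0), (L, -1.0)], 0.0)        # G_{t-1} <= L
        else:
            ub([(j, 1.0), (j + 1, -1.0)], 0.0)
    if t < m:
        ub([(L, 1.0), (t, -1.0)], 0.0)            # L <= G_t
    # convex chain on points 0..t-1 then (u[t], L)
    pts = [(u[j], j) for j in range(t)] + [(u[t], L)]
    for a, bb, c in zip(pts, pts[1:], pts[2:]):
        (xa, ia), (xb, ib), (xc, ic) = a, bb, c
        # slope(b,c) >= slope(a,b):  (Gc-Gb)(xb-xa) - (Gb-Ga)(xc-xb) >= 0
        ub([(ic, -(xb - xa)), (ib, (xb - xa) + (xc - xb)), (ia, -(xc - xb))], 0.0)
    # concave chain from (u[t], G_t) onward
    pts = [(u[j], j) for j in range(t, m)]
    for a, bb, c in zip(pts, pts[1:], pts[2:]):
        (xa, ia), (xb, ib), (xc, ic) = a, bb, c
        ub([(ic, (xb - xa)), (ib, -((xb - xa) + (xc - xb))), (ia, (xc - xb))], 0.0)
    bounds = [(0.0, 1.0)] * nv
    res = linprog(np.zeros(nv), A_ub=np.array(A), b_ub=np.array(b),
                  bounds=bounds, method="highs")
    return res.status == 0


def dip_oracle(x, tol=1e-7):
    x = np.sort(np.asarray(x, float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)
    if len(u) == 1:
        return 0.0
    lo, hi = 0.0, 0.5
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if any(_feasible(u, cum, n, mid, t) for t in range(len(u))):
            hi = mid
        else:
            lo = mid
    return hi
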