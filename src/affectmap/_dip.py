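"""Hartigan & Hartigan's dip statistic of unimodality.

The dip of an empirical CDF F_n is the smallest sup-norm distance from
F_n to any unimodal CDF (convex below the mode, concave above, with an
atom allowed at the mode; a mode inside a data gap can always be slid to
the next data point without changing the sup distance).  Everything is
computed in count units: with u_1 < ... < u_m the distinct values and
l_j / r_j the counts just left / right of u_j, a unimodal CDF at sup
distance d = D/n must thread the band [r_j - D, l_j + D], convexly below
the mode point u_t (with a free left limit in [l_t - D, l_t + D]) and
concavely above it (value in [r_t - D, r_t + D]).

Three ingredients give an exact evaluation:

* band feasibility per side: a convex function fits the left band iff
  the greatest convex minorant of the lower counts stays within 2D of
  the upper counts (shift the minorant up by D), giving the per-mode
  requirement A_t = (1/2) max_{j<t} (r_j - GCM(u_j)); mirrored B_t on
  the right.  ``min_t max(A_t, B_t)`` is a lower bound for n * dip that
  ignores only the junction at the mode.
* junction feasibility: the smallest left-piece value reachable at u_t
  is the upper envelope of the pairwise slope certificates (lower band
  at j2 propagated forward with the steepest slope forced by an upper
  band at j1 < j2); symmetrically the largest right-piece start value.
  The mode works iff smallest-left <= largest-right.
* bisection: the cheap lower bound is almost always feasible and hence
  exact; otherwise dip is bisected between the bound and the global
  maximum 1/4 using the full feasibility check.

The p-value is a bootstrap against the uniform null — the standard
construction; dip is invariant under strictly increasing transforms, so
the uniform law stands in for any unimodal null with continuous CDF.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_test", "dip_null_table"]


def _halfgap_sweep(u: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Per-prefix max gap between ``upper`` and the running convex minorant
    of ``lower``.

    Returns g with g[t] = max_{j < t} (upper[j] - H_t(u[j])), H_t the lower
    convex hull of {(u_i, lower_i) : i <= t}.  g[t] is nondecreasing in t
    (the hull only drops as points are added), which the lazy update relies
    on: only points spanned by a newly created hull segment are rescored.
    """
    m = u.size
    hull: list[int] = []
    g = np.zeros(m)
    best = 0.0
    for t in range(m):
        popped = False
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (u[a] - u[o]) * (lower[t] - lower[o]) \
                - (lower[a] - lower[o]) * (u[t] - u[o])
            if cross <= 0:
                hull.pop()
                popped = True
            else:
                break
        if hull and (popped or t > hull[-1] + 1):
            h = hull[-1]
            span = slice(h + 1, t)
            if span.stop > span.start:
                frac = (u[span] - u[h]) / (u[t] - u[h])
                hull_vals = lower[h] + frac * (lower[t] - lower[h])
                best = max(best, float(np.max(upper[span] - hull_vals)))
        hull.append(t)
        g[t] = best
        # u[t]'s own band gap joins the running max only for later prefixes
        # (as a mode candidate its upper band is relaxed).
        best = max(best, float(upper[t] - lower[t]))
    return g


def _junction_floor(u: np.ndarray, l: np.ndarray, r: np.ndarray, D: float) -> np.ndarray:
    """Minimal left-piece value at each mode candidate u_t, for band D.

    The left piece is convex and nondecreasing with r_j - D <= phi(u_j)
    <= l_j + D for j < t.  Its minimal value at u_t is the upper envelope
    of the certificates phi(u_t) >= a_j2 + s_j2 (u_t - u_j2), where
    a_j = r_j - D and s_j2 = max(0, max_{j1<j2} (a_j2 - b_j1) /
    (u_j2 - u_j1)) is the steepest slope forced below u_j2 by an upper
    band b_j1 = l_j1 + D.  O(m^2), vectorized.
    """
    m = u.size
    a = r - D
    b = l + D
    s = np.zeros(m)
    lext = np.full(m, -np.inf)
    block = 512 if m > 1024 else m  # bound peak memory at large n
    for start in range(0, m, block):
        sl = slice(start, min(start + block, m))
        du = u[sl, None] - u[None, :]       # du[j2, j1] = u_j2 - u_j1
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = (a[sl, None] - b[None, :]) / du
        slopes[du <= 0] = -np.inf           # only j1 < j2
        s[sl] = np.maximum(np.max(slopes, axis=1, initial=0.0), 0.0)
    for start in range(0, m, block):
        sl = slice(start, min(start + block, m))
        du = u[sl, None] - u[None, :]
        # line value of certificate j2 at every u_t > u_j2
        vals = a[None, :] + s[None, :] * du  # [t, j2]
        vals[du <= 0] = -np.inf              # only j2 < t
        lext[sl] = np.max(vals, axis=1, initial=-np.inf)
    return np.maximum(lext, l - D)


def _junction_gap(u, l, r, D) -> np.ndarray:
    """Junction violation lmin - rmax per mode at band D (<= 0: connectable)."""
    n = r[-1]
    lmin = _junction_floor(u, l, r, D)
    # Right side via reflection: x -> -x swaps lower/upper counts.
    rmax = n - _junction_floor(-u[::-1], (n - r)[::-1], (n - l)[::-1], D)[::-1]
    return lmin - rmax




def dip_statistic(values) -> float:
    """Exact dip of the empirical CDF of ``values``.

    Two equal point masses give the maximal dip 0.25; a point mass (all
    values identical) gives 0; the floor for n distinct values is 1/(2n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    u, counts = np.unique(x, return_counts=True)
    r = np.cumsum(counts).astype(float)
    l = r - counts
    gapA = _halfgap_sweep(u, l, r)
    gapB = _halfgap_sweep(-u[::-1], (r[-1] - r)[::-1], (r[-1] - l)[::-1])[::-1]
    sides = np.maximum(gapA, gapB) / 2.0
    D0 = max(float(np.min(sides)), 0.5)
    tol = 1e-9 * n
    cache: dict[float, np.ndarray] = {}

    def gaps(D: float) -> np.ndarray:
        if D not in cache:
            cache[D] = _junction_gap(u, l, r, D)
        return cache[D]

    def excess(D: float) -> float:
        """min over admissible modes of the junction violation (decreasing)."""
        ok = sides <= D + tol
        if not ok.any():
            return np.inf
        return float(np.min(gaps(D)[ok]))

    g0 = excess(D0)
    if g0 <= tol:
        return D0 / n
    # The junction binds at the lower bound.  Per mode the violation falls
    # at rate >= 2 per unit of band half-width, so
    # min_t max(sides_t, D0 + V_t(D0)/2) brackets the root from above;
    # regula falsi (Illinois safeguard) on the decreasing excess function
    # then converges in a handful of vectorized evaluations.
    hi = float(np.min(np.maximum(sides, D0 + np.maximum(gaps(D0), 0.0) / 2.0)))
    lo, g_lo = D0, g0
    g_hi = excess(hi)
    side = 0
    while hi - lo > 1e-7 * n:
        if np.isfinite(g_lo) and g_lo > 0 and g_hi < 0:
            mid = lo + g_lo * (hi - lo) / (g_lo - g_hi)
            mid = min(max(mid, lo + 0.01 * (hi - lo)), hi - 0.01 * (hi - lo))
        else:
            mid = 0.5 * (lo + hi)
        g_mid = excess(mid)
        if g_mid > tol:
            lo, g_lo = mid, g_mid
            if side == -1:
                g_hi *= 0.5  # Illinois trick: avoid endpoint stagnation
            side = -1
        else:
            hi, g_hi = mid, g_mid
            if side == 1:
                g_lo *= 0.5
            side = 1
    return hi / n


def dip_null_table(n: int, n_boot: int = 2000, seed: int | None = None) -> np.ndarray:
    """Bootstrap dips of uniform samples of size n (the null reference).

    The null dip distribution depends only on n, so one table can score
    many observed samples of the same size.
    """
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])


def dip_test(
    values, n_boot: int = 2000, seed: int | None = None,
    null_dips: np.ndarray | None = None,
) -> tuple[float, float]:
    """Dip statistic and its bootstrap p-value against the uniform null.

    ``null_dips`` may carry a precomputed :func:`dip_null_table` for the
    same sample size.  p = (1 + #{null >= dip}) / (1 + n_boot).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("dip test requires at least 4 observations")
    d = dip_statistic(x)
    if null_dips is None:
        null_dips = dip_null_table(x.size, n_boot, seed)
    p = (1.0 + np.sum(null_dips >= d)) / (1.0 + len(null_dips))
    return d, float(p)
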