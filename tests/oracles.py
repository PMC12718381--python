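"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most transparent method
available (exhaustive search, bisection, naive Monte Carlo) and share no
code with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def segment_cost(prefix1: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-segment sum of squared deviations of y[i:j] from its mean."""
    s1 = prefix1[j] - prefix1[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s1 * s1 / (j - i)


def brute_force_change_points(y: np.ndarray, penalty: float,
                              min_segment: int = 4) -> list[int]:
    """Exhaustive least-squares search over all 0-, 1- and 2-step models.

    Enumerates every admissible change-point and change-point pair, applies
    the same penalized-cost selection rule (smallest number of steps wins
    ties), and returns the optimal change-point frames.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    p1 = np.concatenate(([0.0], np.cumsum(y)))
    p2 = np.concatenate(([0.0], np.cumsum(y * y)))

    best0 = segment_cost(p1, p2, 0, n)

    best1, cp1 = np.inf, None
    for c in range(min_segment, n - min_segment + 1):
        cost = segment_cost(p1, p2, 0, c) + segment_cost(p1, p2, c, n)
        if cost < best1:
            best1, cp1 = cost, [c]

    best2, cp2 = np.inf, None
    for c1 in range(min_segment, n - 2 * min_segment + 1):
        left = segment_cost(p1, p2, 0, c1)
        for c2 in range(c1 + min_segment, n - min_segment + 1):
            cost = left + segment_cost(p1, p2, c1, c2) \
                + segment_cost(p1, p2, c2, n)
            if cost < best2:
                best2, cp2 = cost, [c1, c2]

    totals = [best0, best1 + penalty, best2 + 2 * penalty]
    choice = 0
    for m in (1, 2):
        if totals[m] < totals[choice] - 1e-12:
            choice = m
    return [[], cp1, cp2][choice] or []


def bisect_fret_distance(e_target: float, r0: float, lo: float = 1e-6,
                         hi: float = 1e3, tol: float = 1e-12) -> float:
    """Solve E(R) = e_target for R by bisection on E = 1/(1+(R/R0)^6)."""
    def f(r: float) -> float:
        return 1.0 / (1.0 + (r / r0) ** 6) - e_target
    assert f(lo) > 0 > f(hi)
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mc_random_pairing(m: float, h: float, n_subunits: int,
                      rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo heterodimer count from random pairing.

    Returns (estimate scaled to input units, standard error on that scale).
    """
    n = n_subunits - (n_subunits % 2)
    labels = rng.random(n) < m / (m + h)
    pairs = labels.reshape(-1, 2)
    x = float(np.sum(pairs[:, 0] != pairs[:, 1]))
    n_pairs = n / 2.0
    frac = x / n_pairs
    se_frac = np.sqrt(max(frac * (1 - frac), 1e-12) / n_pairs)
    scale = (m + h) / 2.0
    return frac * scale, se_frac * scale
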