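"""Independent brute-force oracles used only by the test suite.

These re-derive expected results by exhaustive enumeration or plain Monte
Carlo, sharing no code path with the library implementation.
"""

from __future__ import annotations

import numpy as np


def oracle_half_life(points, axis="generations", threshold=50.0):
    """Exhaustive-search piecewise-linear half-life.

    Enumerates every admissible (below, above) point pair and applies the
    stated minimization (closest below, then closest above, ties toward the
    tightest bracket); series crossing the threshold more than once use the
    widened pair (last sub-threshold point, first point of the sustained
    recovery). Returns (status, value, smoothing_applied).
    """
    xs = [float(p.generation) if axis == "generations" else p.day for p in points]
    vs = [p.pct_on for p in points]
    above = [v >= threshold for v in vs]
    n = len(points)

    if not any(above):
        return "censored", None, False
    if all(above):
        cands = [(vs[i], xs[i]) for i in range(n) if points[i].generation > 0]
        v_a, x_a = min(cands)
        x_b, v_b = 0.0, 0.0
        value = x_b + (threshold - v_b) * (x_a - x_b) / (v_a - v_b)
        return "left_anchored", value, False
    if not above[-1]:
        return "censored", None, False

    crossings = sum(a != b for a, b in zip(above, above[1:]))
    if crossings == 1:
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(n)
            if vs[i] < threshold <= vs[j] and xs[i] < xs[j]
        ]
        i, j = min(
            pairs,
            key=lambda ij: (
                threshold - vs[ij[0]],
                vs[ij[1]] - threshold,
                -xs[ij[0]],
                xs[ij[1]],
            ),
        )
        smoothing = False
    else:
        j = min(k for k in range(n) if all(above[k:]))
        i = max(k for k in range(n) if not above[k])
        smoothing = True
    value = xs[i] + (threshold - vs[i]) * (xs[j] - xs[i]) / (vs[j] - vs[i])
    status = "left_anchored" if points[i].generation == 0 else "interpolated"
    return status, value, smoothing


def mc_max_abs_tail(t: float, corr: np.ndarray, n_draws: int, seed: int) -> float:
    """Plain Monte-Carlo P(max_i |Z_i| >= t) for Z ~ N(0, corr)."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    Z = rng.standard_normal((n_draws, corr.shape[0])) @ L.T
    return float(np.mean(np.max(np.abs(Z), axis=1) >= t))
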