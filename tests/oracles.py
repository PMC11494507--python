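"""Independent reference estimators used to cross-check the implementation.

These deliberately share no code with the package: a Dijkstra minimax
search over raw grid values checks string-method barriers, and BAR (by
bisection) / exponential averaging check MBAR on two-state problems.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp


def dijkstra_minimax(values: np.ndarray, start_idx, end_idx):
    """Minimax path cost on an 8-connected grid of node energies.

    Returns (barrier_value, (i, j) of the highest node on the optimal
    path).  The cost of a path is the maximum node energy en route; the
    search minimizes that maximum, which is the discrete rate-controlling
    barrier between the two nodes.
    """
    n, m = values.shape
    si, sj = start_idx
    best = np.full((n, m), np.inf)
    best[si, sj] = values[si, sj]
    argmax_node = {(si, sj): (si, sj)}
    pq = [(values[si, sj], (si, sj))]
    while pq:
        c, (i, j) = heapq.heappop(pq)
        if (i, j) == tuple(end_idx):
            return c, argmax_node[(i, j)]
        if c > best[i, j]:
            continue
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < n and 0 <= b < m:
                    nc = max(c, values[a, b])
                    if nc < best[a, b]:
                        best[a, b] = nc
                        argmax_node[(a, b)] = (
                            (a, b) if values[a, b] >= c else argmax_node[(i, j)])
                        heapq.heappush(pq, (nc, (a, b)))
    raise RuntimeError("no path between the requested nodes")


def bar_bisection(w_f: np.ndarray, w_r: np.ndarray, tol: float = 1e-12) -> float:
    """Bennett acceptance ratio Delta f (reduced) solved by bisection.

    ``w_f`` are forward reduced work values u_1(x) - u_0(x) for samples
    from state 0; ``w_r`` reverse work values u_0(x) - u_1(x) for samples
    from state 1.  Solves the implicit BAR equation with the Fermi
    function.
    """
    n_f, n_r = len(w_f), len(w_r)
    M = np.log(n_f / n_r)

    def fermi_balance(df):
        lhs = logsumexp(-np.logaddexp(0.0, M + w_f - df))
        rhs = logsumexp(-np.logaddexp(0.0, -M + w_r + df))
        return lhs - rhs

    lo, hi = -200.0, 200.0
    return brentq(fermi_balance, lo, hi, xtol=tol)


def fep_forward(w_f: np.ndarray) -> float:
    """Exponential-averaging (free-energy perturbation) estimate, reduced."""
    return -(logsumexp(-w_f) - np.log(len(w_f)))
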