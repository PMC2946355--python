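"""Backward-time ancestral Markov chains and the coalescent effective size.

A single lineage traced backward through the age-structured semelparous
population performs a Markov chain on the age classes: from class ``i >= 2``
it moves deterministically to class ``i-1`` (it was one year younger the
year before), and from class 1 it jumps to the age class of its parent,
class ``m`` with probability ``p_m``.  Two lineages move as the Kronecker
square of this chain, except that whenever both sit in class 1 they may have
picked the same parent — the same individual among the ``D_m = c_m N`` dying
adults of class ``m`` — and coalesce, with probability of order ``1/N``.

The order-of-magnitude gap between the movement (O(1)) and coalescence
(O(1/N)) probabilities is a two-time-scale structure: writing the
two-lineage transition matrix as ``Pi_N = A + B/N + O(1/N^2)``, the limit
theorem for such chains gives weak convergence of the rescaled ancestral
process to a continuous-time chain with generator ``G = P B P``, where
``P = lim_n A^n`` (Cesàro limit when the fast chain is periodic).  Every
transient row of ``P`` is the product ``pi x pi`` of the single-lineage
stationary distribution with itself, so the pair coalescence rate per year
is ``(1/g^2) * sum_m p_m^2 / c_m`` in units of ``N`` years, with ``g`` the
generation length.  The coalescent effective population size follows in
closed form::

    N_e = N * g / sum_m (p_m^2 / c_m)

which reduces to ``N_e = N`` both for a single reproductive class with
equal class sizes and for the conservative weighting ``p_m = m * c_m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .life_history import LifeHistory, generation_length, validate

__all__ = [
    "SingleLineageMatrix",
    "TwoLineageChain",
    "MohleLimit",
    "build_xi",
    "stationary",
    "period",
    "kron",
    "build_two_lineage",
    "mohle_limit",
    "ces",
    "ces_surface",
    "tradeoff_grid",
    "mean_absorption_time",
    "absorption_times",
]


@dataclass(frozen=True)
class SingleLineageMatrix:
    """Transition matrix of one backward lineage over age classes 1..k."""

    xi: np.ndarray
    p: np.ndarray

    @property
    def k(self) -> int:
        return self.xi.shape[0]

    def is_irreducible(self) -> bool:
        graph = csr_matrix(self.xi > 0)
        n_comp, _ = connected_components(graph, directed=True, connection="strong")
        return n_comp == 1


@dataclass(frozen=True)
class TwoLineageChain:
    """Two labeled lineages over the k^2 ordered-pair states plus absorbing C.

    ``Pi_N`` is the exact finite-N transition matrix, ``A`` its large-N limit
    (fast process: Kronecker square of the single-lineage matrix on the
    transient block) and ``B`` the slow-process matrix
    ``lim N * (Pi_N - A)``, nonzero only in the row of state ``(1, 1)``.
    """

    states: tuple
    Pi_N: np.ndarray
    A: np.ndarray
    B: np.ndarray
    D: np.ndarray
    N: float

    @property
    def k(self) -> int:
        return int(round(len(self.D)))

    def index(self, state) -> int:
        return self.states.index(state)


@dataclass(frozen=True)
class MohleLimit:
    """Pieces of the two-time-scale limit: P, the generator G = PBP, pi."""

    P: np.ndarray
    G: np.ndarray
    pi: np.ndarray
    ces_rate: float


def build_xi(lh: LifeHistory) -> SingleLineageMatrix:
    """Single-lineage backward transition matrix.

    Row 1 is the contribution vector ``p``; row ``i >= 2`` is the unit vector
    on column ``i-1`` (deterministic aging backward).
    """
    k = lh.k
    xi = np.zeros((k, k))
    xi[0] = lh.p
    xi[np.arange(1, k), np.arange(0, k - 1)] = 1.0
    return SingleLineageMatrix(xi=xi, p=lh.p.copy())


def period(xi: SingleLineageMatrix) -> int:
    """Period of the lineage chain: gcd of the reproductive-age support.

    Return times to class 1 are exactly the parental ages, so the chain is
    aperiodic iff the ages with ``p_m > 0`` have gcd 1 (e.g. it is periodic
    with period k when only the last class reproduces).
    """
    ages = np.flatnonzero(xi.p > 0) + 1
    out = 0
    for a in ages:
        out = gcd(out, int(a))
    return max(out, 1)


def stationary(xi: SingleLineageMatrix) -> np.ndarray:
    """Stationary distribution of the single-lineage chain.

    Computed in closed form from the expected return time to class 1:
    ``pi_i = (sum_{j >= i} p_j) / g``.  In particular ``pi_1 = 1/g``: a
    backward lineage spends one year in class 1 per generation.

    Raises
    ------
    ValueError
        If the chain is reducible (requires ``p_k > 0`` so the oldest class
        is reachable), in which case no unique stationary distribution
        exists on the full state space.
    """
    if not xi.is_irreducible():
        raise ValueError(
            "no unique stationary distribution: single-lineage chain is "
            "reducible (the oldest age class must have p_k > 0)"
        )
    g = float(np.dot(np.arange(1, xi.k + 1), xi.p))
    return np.cumsum(xi.p[::-1])[::-1] / g


def kron(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Kronecker product with the block structure ``[U_ab * V]_ab``."""
    return np.kron(np.asarray(U), np.asarray(V))


def _check(lh: LifeHistory) -> None:
    problems = validate(lh)
    if problems:
        raise ValueError("invalid life history: " + "; ".join(problems))


def pair_states(k: int) -> tuple:
    """Ordered-pair states in lexicographic order, absorbing ``'C'`` last."""
    return tuple((i, j) for i in range(1, k + 1) for j in range(1, k + 1)) + ("C",)


def build_two_lineage(lh: LifeHistory, N: float | None = None) -> TwoLineageChain:
    """Exact finite-N two-lineage chain plus its A/B decomposition.

    The finite-N coalescence entries use integer parent-pool sizes
    ``D_m = round(c_m * N)`` clipped to at least 1, which keeps ``Pi_N`` a
    true stochastic matrix at small ``N``; the analytic ``B`` uses the exact
    ``c_m``.
    """
    _check(lh)
    if N is None:
        N = lh.N
    k = lh.k
    p, c = lh.p, lh.c
    repro = np.flatnonzero(p > 0)
    D = np.zeros(k)
    D[repro] = np.maximum(1, np.round(c[repro] * N))
    states = pair_states(k)
    n = k * k + 1
    C = n - 1

    def idx(i: int, j: int) -> int:
        return (i - 1) * k + (j - 1)

    Pi = np.zeros((n, n))
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for i in range(1, k + 1):
        for j in range(1, k + 1):
            r = idx(i, j)
            if i >= 2 and j >= 2:
                Pi[r, idx(i - 1, j - 1)] = 1.0
            elif i == 1 and j >= 2:
                for m in repro + 1:
                    Pi[r, idx(m, j - 1)] = p[m - 1]
            elif i >= 2 and j == 1:
                for m in repro + 1:
                    Pi[r, idx(i - 1, m)] = p[m - 1]
            else:  # (1, 1): both lineages pick a parental class and a parent
                for m in repro + 1:
                    pm = p[m - 1]
                    Pi[r, idx(m, m)] += pm * pm * (1.0 - 1.0 / D[m - 1])
                    Pi[r, C] += pm * pm / D[m - 1]
                    B[r, idx(m, m)] = -pm * pm / c[m - 1]
                    for l in repro + 1:
                        if l != m:
                            Pi[r, idx(m, l)] += pm * p[l - 1]
                B[r, C] = lh.sum_p2_over_c()
    A[: C, : C] = np.kron(build_xi(lh).xi, build_xi(lh).xi)
    Pi[C, C] = 1.0
    A[C, C] = 1.0
    return TwoLineageChain(states=states, Pi_N=Pi, A=A, B=B, D=D, N=float(N))


def mohle_limit(chain: TwoLineageChain, lh: LifeHistory) -> MohleLimit:
    """Two-time-scale limit of the two-lineage chain.

    ``P`` is built analytically: every transient row equals ``pi (x) pi`` on
    the transient columns and 0 on C (the fast process never coalesces), and
    the C row is absorbing.  When the fast chain is periodic this is its
    Cesàro (time-average) limit rather than the plain power limit.  The
    generator is ``G = P B P`` and the pair coalescence rate per generation
    on the N-year timescale is ``(1/g^2) * sum p_m^2 / c_m``.
    """
    pi = stationary(build_xi(lh))
    n = chain.Pi_N.shape[0]
    P = np.zeros((n, n))
    P[:-1, :-1] = np.tile(np.kron(pi, pi), (n - 1, 1))
    P[-1, -1] = 1.0
    G = P @ chain.B @ P
    g = generation_length(lh)
    return MohleLimit(P=P, G=G, pi=pi, ces_rate=lh.sum_p2_over_c() / g**2)


def ces(lh: LifeHistory) -> float:
    """Coalescent effective population size ``N_e = N g / sum_m p_m^2/c_m``.

    This is the size such that, with time in units of ``N_e`` generations
    (``N_e * g`` years), the pair genealogy converges to Kingman's coalescent
    with rate 1.
    """
    _check(lh)
    return lh.N * generation_length(lh) / lh.sum_p2_over_c()


def tradeoff_grid(
    p5_values,
    c5_values,
    p3: float = 0.1,
    p45_total: float = 0.9,
) -> list[tuple[float, float, float]]:
    """Grid of ``(p4, p5, c5)`` points with ``p4 + p5`` fixed.

    Matches the published surface exploration where ``p3`` is fixed and the
    adult contributions trade off against each other.
    """
    return [
        (p45_total - p5, float(p5), float(c5))
        for p5 in np.asarray(p5_values, dtype=float)
        for c5 in np.asarray(c5_values, dtype=float)
    ]


def ces_surface(
    grid,
    p3: float = 0.1,
    c3: float = 0.05,
    c4: float = 0.1,
    N: float = 1000.0,
    n_juvenile: int = 2,
) -> pd.DataFrame:
    """Evaluate the CES over a grid of ``(p4, p5, c5)`` points.

    Returns one row per grid point with columns ``p4, p5, c5, Ne, feasible``.
    Infeasible points (contributions not summing to 1, negative entries, or
    a reproducing class with zero deaths) are flagged, not dropped; their
    ``Ne`` is NaN.
    """
    rows = []
    for p4, p5, c5 in grid:
        p = np.array([0.0, 0.0, p3, p4, p5])
        c = np.array([0.0, 0.0, c3, c4, c5])
        lh = LifeHistory(p=p, c=c, N=N, n_juvenile=n_juvenile)
        feasible = not validate(lh)
        ne = ces(lh) if feasible else np.nan
        rows.append((p4, p5, c5, ne, feasible))
    return pd.DataFrame(rows, columns=["p4", "p5", "c5", "Ne", "feasible"])


def absorption_times(chain: TwoLineageChain) -> np.ndarray:
    """Expected years to coalescence from every transient state.

    Solves ``(I - T) t = 1`` on the transient block by dense LU.  States from
    which the absorbing state is unreachable (possible when the lineage chain
    is periodic and the two lineages are out of phase) get ``inf`` rather
    than a spurious finite value.
    """
    n = chain.Pi_N.shape[0]
    T = chain.Pi_N[:-1, :-1]
    # backward reachability of C over the directed transition graph
    reach = chain.Pi_N[:-1, -1] > 0
    adj = T > 0
    while True:
        new = reach | (adj[:, reach].any(axis=1))
        if np.array_equal(new, reach):
            break
        reach = new
    t = np.full(n - 1, np.inf)
    if reach.any():
        sub = np.flatnonzero(reach)
        t[sub] = np.linalg.solve(np.eye(len(sub)) - T[np.ix_(sub, sub)], np.ones(len(sub)))
    return t


def mean_absorption_time(
    chain: TwoLineageChain, lh: LifeHistory, init: str = "stationary"
) -> float:
    """Mean years to coalescence from a sampling distribution over pairs.

    ``init="stationary"`` weights the ordered-pair states by ``pi (x) pi``;
    ``init="uniform-sample"`` draws two distinct individuals uniformly from
    the population (weights ``N_i N_j`` off-diagonal, ``N_i (N_i - 1)`` on).
    A specific state tuple ``(i, j)`` is also accepted.
    """
    t = absorption_times(chain)
    k = lh.k
    if isinstance(init, tuple):
        return float(t[(init[0] - 1) * k + (init[1] - 1)])
    if init == "stationary":
        pi = stationary(build_xi(lh))
        w = np.kron(pi, pi)
    elif init == "uniform-sample":
        sizes = lh.class_sizes
        w = np.outer(sizes, sizes) - np.diag(sizes)
        w = (w / w.sum()).ravel()
    else:
        raise ValueError(f"unknown init {init!r}")
    # 0 * inf would poison the mean from states carrying no sampling mass
    return float(np.sum(np.where(w > 0, w * t, 0.0)))
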