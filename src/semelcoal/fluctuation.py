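"""Fast i.i.d. fluctuations in total population size.

Salmon population sizes swing strongly from year to year, on a time scale
far shorter than coalescence (which takes order ``N`` generations).  Here
the yearly total size is ``N * x_t`` with multipliers ``x_t`` drawn i.i.d.
from a finite set of atoms ``(x_j, q_j)``; the demographic fractions ``p``
and ``c`` stay fixed and every age class scales linearly with the total.
Coalescence probability in a year of size ``N x`` is inversely proportional
to ``x``, so averaging the per-year no-coalescence probability over the size
law replaces ``N`` by the harmonic mean ``H = N / sum_j (q_j / x_j)``: the
long-term coalescent effective size is the constant-size formula evaluated
at ``H``::

    N_e = g * H / sum_m (p_m^2 / c_m)

This module also implements the two classical breeder-based estimators for a
yearly size series — ``g`` times the harmonic mean of the yearly effective
number of breeders (valid when each year's spawners contribute equally to
the next generation) and ``g`` times their arithmetic mean (valid when
contributions are proportional to spawner numbers) — and a per-generation
comparison of the two with the coalescent value on simulated series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hmean

from .ancestral_chain import build_xi, ces, period
from .coalescent_sim import (
    CoalescenceSample,
    _check,
    _init_states,
    _pair_renewal_times,
)
from .life_history import LifeHistory, breeders, generation_length

__all__ = [
    "SizeProcess",
    "EstimateTable",
    "longterm_ces",
    "waples_harmonic",
    "waples_arithmetic",
    "simulate_series",
    "compare_estimates",
    "simulate_fluctuating_pair",
]


@dataclass(frozen=True)
class SizeProcess:
    """Finite-atom i.i.d. law of the yearly size multiplier.

    The population size in year ``t`` is ``baseline_N * x_j`` with
    probability ``q_j``, independently across years.
    """

    x: np.ndarray
    q: np.ndarray
    baseline_N: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        if self.x.shape != self.q.shape or self.x.ndim != 1:
            raise ValueError("x and q must be 1-d vectors of equal length")
        if np.any(self.x <= 0):
            raise ValueError("size multipliers x must be positive")
        if abs(self.q.sum() - 1.0) > 1e-12 or np.any(self.q < 0):
            raise ValueError("atom probabilities q must be non-negative and sum to 1")

    @property
    def harmonic_mean_size(self) -> float:
        """Harmonic mean of the yearly sizes, ``N / E[1/x]``."""
        return float(self.baseline_N / np.sum(self.q / self.x))

    @property
    def arithmetic_mean_size(self) -> float:
        return float(self.baseline_N * np.sum(self.q * self.x))


@dataclass(frozen=True)
class EstimateTable:
    """Per-generation-block estimates for a yearly size series.

    ``table`` has one row per full block with the block's breeder-count
    means and the three effective-size estimates; the arithmetic estimate
    assumes equal yearly contributions regardless of abundance, the harmonic
    estimate proportional contributions, and the coalescent column applies
    the long-term CES formula to the block's empirical size distribution.
    """

    table: pd.DataFrame
    dropped_years: int
    g: float
    breeder_fraction: float
    whole_series: dict


def longterm_ces(lh: LifeHistory, sp: SizeProcess) -> float:
    """Long-term coalescent effective size under fast i.i.d. size noise.

    ``g * H / sum_m p_m^2/c_m`` with ``H`` the harmonic mean of the yearly
    sizes; equal to the constant-size CES when all multipliers are 1.
    """
    _check(lh)
    return ces(lh.rescaled(sp.harmonic_mean_size))


def waples_harmonic(nb_series, g: float) -> float:
    """Effective size as generation length times the harmonic mean of the
    yearly effective numbers of breeders (equal-contribution assumption)."""
    nb = np.asarray(nb_series, dtype=float)
    if np.any(nb <= 0):
        raise ValueError("breeder counts must be positive")
    return float(g * hmean(nb))


def waples_arithmetic(nb_series, g: float) -> float:
    """Effective size as generation length times the arithmetic mean of the
    yearly effective numbers of breeders (proportional-contribution
    assumption)."""
    nb = np.asarray(nb_series, dtype=float)
    if np.any(nb <= 0):
        raise ValueError("breeder counts must be positive")
    return float(g * nb.mean())


def simulate_series(
    low: int, high: int, years: int, seed: int | None = None
) -> np.ndarray:
    """I.i.d. uniform integer yearly population sizes on ``[low, high]``."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    return rng.integers(low, high, size=years, endpoint=True)


def compare_estimates(
    series,
    lh: LifeHistory,
    block_years: int | None = None,
    n_blocks: int | None = None,
) -> EstimateTable:
    """Blockwise comparison of the three effective-size estimates.

    The series is cut into consecutive blocks of ``block_years`` years
    (default: generation length rounded to the nearest year); a trailing
    partial block is dropped and reported, and ``n_blocks`` truncates to the
    first ``n_blocks`` full blocks.
    """
    _check(lh)
    series = np.asarray(series, dtype=float)
    g = generation_length(lh)
    if block_years is None:
        block_years = int(round(g))
    if block_years < 1:
        raise ValueError("block_years must be >= 1")
    if len(series) < block_years:
        raise ValueError("series shorter than one block")
    frac = float(lh.c[lh.n_juvenile:].sum())  # breeders per individual
    total = len(series) // block_years
    truncated = n_blocks is not None and n_blocks < total
    if truncated:
        total = n_blocks
    used = total * block_years
    dropped = len(series) - used
    if dropped and not truncated:
        warnings.warn(
            f"dropping {dropped} trailing year(s) not filling a {block_years}-year block",
            stacklevel=2,
        )
    S = lh.sum_p2_over_c()
    rows = []
    for b in range(total):
        block = series[b * block_years : (b + 1) * block_years]
        nb = frac * block
        rows.append(
            {
                "block": b + 1,
                "start_year": b * block_years + 1,
                "end_year": (b + 1) * block_years,
                "Nb_arith": nb.mean(),
                "Nb_harm": hmean(nb),
                "est_A": waples_arithmetic(nb, g),
                "est_H": waples_harmonic(nb, g),
                "est_C": g * hmean(block) / S,
            }
        )
    nb_all = frac * series[:used]
    whole = {
        "est_A": waples_arithmetic(nb_all, g),
        "est_H": waples_harmonic(nb_all, g),
        "est_C": g * hmean(series[:used]) / S,
        "years_used": used,
    }
    return EstimateTable(
        table=pd.DataFrame(rows),
        dropped_years=dropped,
        g=g,
        breeder_fraction=frac,
        whole_series=whole,
    )


def simulate_fluctuating_pair(
    lh: LifeHistory,
    sp: SizeProcess,
    reps: int = 1000,
    seed: int | None = None,
    init="stationary",
) -> CoalescenceSample:
    """Backward pair walk with the yearly size redrawn i.i.d. from ``sp``.

    Identical to the constant-size pair simulator except that in each year
    both lineages visit age class 1 together, the coalescence probability
    uses that year's parent pools ``D_m = round(c_m * N * x)`` with ``x``
    drawn from the size process.  The mean absorption time matches the
    harmonic-mean long-term CES.
    """
    _check(lh)
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    repro = lh.p > 0
    min_pool = sp.baseline_N * sp.x.min() * lh.c[repro].min()
    if min_pool < 1:
        raise ValueError(
            "baseline_N * min(x) too small: some year would have an empty "
            f"spawner pool (smallest expected pool {min_pool:.3g})"
        )
    rng = np.random.default_rng(seed)
    q = period(build_xi(lh))
    i0, j0 = _init_states(lh, sp.baseline_N, reps, init, rng)
    cum_p = np.cumsum(lh.p)
    cum_q = np.cumsum(sp.q)
    c = lh.c

    def coal_prob(r: np.random.Generator, ages: np.ndarray) -> np.ndarray:
        x = sp.x[np.searchsorted(cum_q, r.random(ages.size), side="right")]
        D = np.maximum(1.0, np.round(c[ages - 1] * sp.baseline_N * x))
        return 1.0 / D

    times = _pair_renewal_times(rng, cum_p, i0 - 1, j0 - 1, coal_prob, q)
    return CoalescenceSample(
        times_years=times,
        n_lineages=2,
        seed=seed,
        settings={
            "N": float(sp.baseline_N),
            "init": init,
            "atoms": list(zip(sp.x.tolist(), sp.q.tolist())),
        },
    )
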