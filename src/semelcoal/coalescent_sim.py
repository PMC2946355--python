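"""Monte-Carlo engines for the semelparous ancestral process.

Two independent routes to pair-coalescence times are provided:

* an exact backward-time simulator of the finite-N two-lineage chain.  The
  default ``"renewal"`` method exploits the chain's structure — between
  visits to age class 1 a lineage moves deterministically, so the class-1
  visit years of each lineage form a renewal process whose increments are
  the parental ages drawn from ``p``; coalescence can only be attempted in
  years when both lineages visit class 1 together.  Skipping the
  deterministic stretches gives the same law as stepping the 26-state chain
  year by year (the ``"chain"`` method, kept as a slow reference) at a small
  fraction of the cost.
* a forward Wright-Fisher simulator with explicit individuals and a full
  pedigree of first-age-class cohorts, from which pair TMRCAs and
  parent-sharing probabilities are measured independently of any backward
  construction.

When only a single age class reproduces the lineage chain is periodic and
two lineages whose class-1 visit years differ modulo the period can never
coalesce; such replicates honestly return ``inf`` instead of looping
forever.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .ancestral_chain import build_two_lineage, build_xi, period, stationary
from .life_history import LifeHistory, generation_length, validate

__all__ = [
    "CoalescenceSample",
    "NLineageSample",
    "ForwardPedigree",
    "simulate_pair_backward",
    "simulate_n_backward",
    "simulate_forward",
]


@dataclass(frozen=True)
class CoalescenceSample:
    """Replicate pair-coalescence times in years, with run settings."""

    times_years: np.ndarray
    n_lineages: int
    seed: int
    settings: dict

    def summary(self) -> dict:
        """Mean/sd/SE over finite replicates plus the never-coalescing count."""
        t = self.times_years
        finite = t[np.isfinite(t)]
        n = len(finite)
        sd = float(finite.std(ddof=1)) if n > 1 else float("nan")
        return {
            "reps": len(t),
            "n_finite": n,
            "mean": float(finite.mean()) if n else float("inf"),
            "sd": sd,
            "se": sd / np.sqrt(n) if n > 1 else float("nan"),
            "n_never": int(len(t) - n),
        }


@dataclass(frozen=True)
class NLineageSample:
    """Per-replicate sorted merge times for a sample of n lineages."""

    merge_times: list
    multiple_merger_replicates: int
    n_lineages: int
    seed: int
    settings: dict

    @property
    def reps(self) -> int:
        return len(self.merge_times)


def _check(lh: LifeHistory) -> None:
    problems = validate(lh)
    if problems:
        raise ValueError("invalid life history: " + "; ".join(problems))


def _parent_pools(lh: LifeHistory, N: float) -> np.ndarray:
    """Integer parent-pool sizes, matching the finite-N chain convention."""
    D = np.zeros(lh.k)
    repro = lh.p > 0
    D[repro] = np.maximum(1, np.round(lh.c[repro] * N))
    return D


def _draw_ages(rng: np.random.Generator, cum_p: np.ndarray, size: int) -> np.ndarray:
    """Parental ages (1-based) sampled from p."""
    return np.searchsorted(cum_p, rng.random(size), side="right") + 1


def _init_states(
    lh: LifeHistory, N: float, reps: int, init, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Initial age classes (1-based) for the two lineages."""
    if isinstance(init, tuple):
        i = np.full(reps, init[0], dtype=np.int64)
        j = np.full(reps, init[1], dtype=np.int64)
        return i, j
    if init == "stationary":
        pi = stationary(build_xi(lh))
        cum = np.cumsum(pi)
        i = np.searchsorted(cum, rng.random(reps), side="right") + 1
        j = np.searchsorted(cum, rng.random(reps), side="right") + 1
        return i.astype(np.int64), j.astype(np.int64)
    if init == "uniform-sample":
        sizes = np.maximum(np.round(lh.rescaled(N).class_sizes), 0)
        w = np.outer(sizes, sizes) - np.diag(sizes)
        w = w.ravel() / w.sum()
        pair = rng.choice(len(w), size=reps, p=w)
        k = lh.k
        return (pair // k + 1).astype(np.int64), (pair % k + 1).astype(np.int64)
    raise ValueError(f"unknown init {init!r}")


def _pair_renewal_times(
    rng: np.random.Generator,
    cum_p: np.ndarray,
    a1: np.ndarray,
    a2: np.ndarray,
    coal_prob: Callable[[np.random.Generator, np.ndarray], np.ndarray],
    chain_period: int,
) -> np.ndarray:
    """Event-driven pair walk on class-1 visit years.

    ``a1``/``a2`` hold the next class-1 visit year of each lineage.  The
    lagging lineage renews with an age drawn from ``p``; on a tie both
    lineages visit class 1 in the same year, draw parental ages, and —
    if the ages agree — coalesce with probability ``coal_prob`` (both chose
    the same parent).  Coalescence is recorded one year after the shared
    class-1 visit, matching the chain's transition into the absorbing state.
    """
    reps = a1.size
    times = np.full(reps, np.inf)
    active = np.ones(reps, dtype=bool)
    if chain_period > 1:
        # visit years only ever shift by multiples of the period
        active &= (a1 - a2) % chain_period == 0
    while True:
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        t1 = a1[idx]
        t2 = a2[idx]
        eq = t1 == t2
        tie = idx[eq]
        if tie.size:
            m1 = _draw_ages(rng, cum_p, tie.size)
            m2 = _draw_ages(rng, cum_p, tie.size)
            prob = np.zeros(tie.size)
            same = m1 == m2
            if same.any():
                prob[same] = coal_prob(rng, m1[same])
            coal = rng.random(tie.size) < prob
            hit = tie[coal]
            times[hit] = a1[hit] + 1.0
            active[hit] = False
            surv = tie[~coal]
            a1[surv] += m1[~coal]
            a2[surv] += m2[~coal]
        lag1 = idx[t1 < t2]
        if lag1.size:
            a1[lag1] += _draw_ages(rng, cum_p, lag1.size)
        lag2 = idx[t1 > t2]
        if lag2.size:
            a2[lag2] += _draw_ages(rng, cum_p, lag2.size)
    return times


def _pair_chain_times(
    lh: LifeHistory,
    N: float,
    rng: np.random.Generator,
    i0: np.ndarray,
    j0: np.ndarray,
    chain_period: int,
) -> np.ndarray:
    """Reference walker: step the exact 26-state chain year by year."""
    chain = build_two_lineage(lh, N)
    cum = np.cumsum(chain.Pi_N, axis=1)
    k = lh.k
    absorbing = k * k
    state = ((i0 - 1) * k + (j0 - 1)).astype(np.int64)
    reps = state.size
    times = np.full(reps, np.inf)
    active = np.ones(reps, dtype=bool)
    if chain_period > 1:
        active &= (i0 - j0) % chain_period == 0
    year = 0
    while active.any():
        year += 1
        idx = np.flatnonzero(active)
        u = rng.random(idx.size)
        nxt = (cum[state[idx]] <= u[:, None]).sum(axis=1)
        state[idx] = nxt
        done = idx[nxt == absorbing]
        times[done] = year
        active[done] = False
    return times


def simulate_pair_backward(
    lh: LifeHistory,
    N: float | None = None,
    reps: int = 1000,
    seed: int | None = None,
    init="stationary",
    method: str = "renewal",
) -> CoalescenceSample:
    """Sample pair-coalescence times from the exact finite-N ancestral chain.

    Parameters
    ----------
    init : tuple, "stationary" or "uniform-sample"
        Starting age classes of the two lineages: a fixed ordered pair, the
        stationary law ``pi (x) pi`` of the backward movement, or two
        distinct individuals drawn uniformly from the whole population.
    method : "renewal" or "chain"
        Event-driven engine (default) or the year-by-year reference walker;
        the two are distributionally identical.

    Replicates that can never coalesce (periodic lineage chain with
    mismatched phases) are reported as ``inf``.
    """
    _check(lh)
    if N is None:
        N = lh.N
    if N < 2:
        raise ValueError("need N >= 2 to sample two distinct lineages")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    q = period(build_xi(lh))
    i0, j0 = _init_states(lh, N, reps, init, rng)
    if method == "chain":
        times = _pair_chain_times(lh, N, rng, i0, j0, q)
    elif method == "renewal":
        D = _parent_pools(lh, N)
        cum_p = np.cumsum(lh.p)

        def coal_prob(r: np.random.Generator, ages: np.ndarray) -> np.ndarray:
            return 1.0 / D[ages - 1]

        times = _pair_renewal_times(rng, cum_p, i0 - 1, j0 - 1, coal_prob, q)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CoalescenceSample(
        times_years=times,
        n_lineages=2,
        seed=seed,
        settings={"N": float(N), "init": init, "method": method},
    )


def simulate_n_backward(
    lh: LifeHistory,
    N: float,
    n_lineages: int,
    reps: int = 1000,
    seed: int | None = None,
) -> NLineageSample:
    """Backward simulation for a small sample of n lineages.

    Lineages visiting age class 1 in the same year independently choose a
    parental class (per ``p``) and a parent uniformly among that year's
    ``D_m`` spawners; lineages choosing the same parent merge.  Multiple
    mergers (three or more lineages on one parent) are possible at finite N;
    replicates containing one are counted.  Requires ``n_lineages`` much
    smaller than ``N`` (at most N/100).
    """
    _check(lh)
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    if n_lineages > 0.01 * N:
        raise ValueError(
            f"sample size {n_lineages} too large for N={N}; need n <= 0.01*N"
        )
    q = period(build_xi(lh))
    if q > 1:
        raise ValueError(
            "periodic life history (single reproductive age support); "
            "out-of-phase lineages can never coalesce"
        )
    rng = np.random.default_rng(seed)
    D = _parent_pools(lh, N)
    cum_p = np.cumsum(lh.p)
    pi = stationary(build_xi(lh))
    cum_pi = np.cumsum(pi)
    # next class-1 visit year per lineage, from stationary starting classes
    T = np.searchsorted(
        cum_pi, rng.random((reps, n_lineages)), side="right"
    ).astype(float)
    active = np.ones((reps, n_lineages), dtype=bool)
    merge_times: list[list[float]] = [[] for _ in range(reps)]
    multi = np.zeros(reps, dtype=bool)
    while True:
        n_active = active.sum(axis=1)
        live = n_active >= 2
        if not live.any():
            break
        Tm = np.where(active & live[:, None], T, np.inf)
        tmin = Tm.min(axis=1)
        at_min = (Tm == tmin[:, None]) & np.isfinite(Tm)
        rows, cols = np.nonzero(at_min)
        ages = _draw_ages(rng, cum_p, rows.size)
        T[rows, cols] += ages
        counts = at_min.sum(axis=1)
        for r in np.flatnonzero(counts >= 2):
            sel = rows == r
            lineages = cols[sel]
            their_ages = ages[sel]
            parents = np.array(
                [rng.integers(0, int(D[m - 1])) for m in their_ages]
            )
            keys = their_ages * (int(D.max()) + 1) + parents
            order = np.argsort(keys, kind="stable")
            keys_sorted = keys[order]
            lin_sorted = lineages[order]
            start = 0
            for end in range(1, len(keys_sorted) + 1):
                if end == len(keys_sorted) or keys_sorted[end] != keys_sorted[start]:
                    size = end - start
                    if size >= 2:
                        for drop in lin_sorted[start + 1 : end]:
                            active[r, drop] = False
                            merge_times[r].append(float(tmin[r]) + 1.0)
                        if size >= 3:
                            multi[r] = True
                    start = end
    return NLineageSample(
        merge_times=[np.array(sorted(m)) for m in merge_times],
        multiple_merger_replicates=int(multi.sum()),
        n_lineages=n_lineages,
        seed=seed,
        settings={"N": float(N)},
    )


# ---------------------------------------------------------------------------
# forward Wright-Fisher oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForwardPedigree:
    """Parental pedigree of first-age-class cohorts from a forward run.

    Cohort ``t`` (``1 <= t <= years``) holds the newborns entering class 1 in
    year ``t``; ``parent_class[t-1][i]`` is the age class of newborn ``i``'s
    parent and ``parent_index[t-1][i]`` the parent's own index within the
    cohort born ``parent_class`` years earlier.  Cohorts with non-positive
    birth year predate the recorded pedigree (tracing stops there).
    """

    cohort_size: int
    years: int
    parent_class: np.ndarray  # (years, cohort_size) int8
    parent_index: np.ndarray  # (years, cohort_size) int32
    pools: np.ndarray  # parent-pool size per class
    seed: int
    settings: dict

    def newborn_counts_by_class(self) -> np.ndarray:
        """Per-year counts of newborns parented by each age class."""
        k = len(self.pools)
        out = np.zeros((self.years, k), dtype=np.int64)
        for m in range(1, k + 1):
            out[:, m - 1] = (self.parent_class == m).sum(axis=1)
        return out

    def pair_coalescence_probability(self) -> np.ndarray:
        """Exact per-year probability that two random newborns share a parent.

        For each cohort, sums ``C(n_p, 2)`` over parents ``p`` with ``n_p``
        offspring, divided by ``C(N_1, 2)``.
        """
        n1 = self.cohort_size
        denom = n1 * (n1 - 1) / 2.0
        big = int(self.parent_index.max()) + 2
        out = np.empty(self.years)
        for t in range(self.years):
            key = self.parent_class[t].astype(np.int64) * big + self.parent_index[t]
            _, counts = np.unique(key, return_counts=True)
            out[t] = (counts * (counts - 1) / 2.0).sum() / denom
        return out

    def sample_pair_tmrca(
        self, n_pairs: int, seed: int, cohort: int | None = None
    ) -> np.ndarray:
        """Pedigree TMRCA (years) of random newborn pairs from one cohort.

        The coalescence year is the latest year in which both ancestral
        lineages are the same individual: one year before the younger of the
        two child lineages descending from the common ancestor was born.
        Pairs whose ancestry leaves the recorded pedigree are NaN.
        """
        rng = np.random.default_rng(seed)
        t0 = self.years if cohort is None else cohort
        out = np.empty(n_pairs)
        for s in range(n_pairs):
            a, b = rng.choice(self.cohort_size, size=2, replace=False)
            seen: dict[tuple[int, int], int] = {}
            y, i = t0, int(a)
            child_birth = t0 + 1  # sentinel: sampling year acts as entry year
            while y >= 1:
                seen[(y, i)] = child_birth
                m = int(self.parent_class[y - 1, i])
                child_birth = y
                i = int(self.parent_index[y - 1, i])
                y = y - m
            y, i = t0, int(b)
            child_birth = t0 + 1
            res = np.nan
            while y >= 1:
                if (y, i) in seen:
                    u = min(seen[(y, i)], child_birth)
                    res = t0 - (u - 1)
                    break
                m = int(self.parent_class[y - 1, i])
                child_birth = y
                i = int(self.parent_index[y - 1, i])
                y = y - m
            out[s] = res
        return out


def simulate_forward(
    lh: LifeHistory,
    N: float | None = None,
    years: int = 100,
    seed: int | None = None,
    quota: str = "multinomial",
) -> ForwardPedigree:
    """Forward Wright-Fisher evolution of the age-structured population.

    Each year, ``D_i`` uniformly chosen individuals die in class ``i``
    (deaths in reproductive classes are that year's spawners), survivors age
    one class, and ``N_1`` newborns each draw a parental class (multinomially
    per ``p`` by default, or by fixed largest-remainder quotas) and then a
    parent uniformly among that class's spawners.  Requires the strict
    integer bookkeeping: every ``c_i * N`` and class size must be a whole
    number and the class sizes must sum to ``N``.
    """
    _check(lh)
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if N is None:
        N = lh.N
    lhN = lh.rescaled(N)
    D_real = lhN.D
    sizes_real = lhN.class_sizes
    if np.any(np.abs(D_real - np.round(D_real)) > 1e-6) or np.any(
        np.abs(sizes_real - np.round(sizes_real)) > 1e-6
    ):
        raise ValueError("forward simulation needs integer class sizes and deaths")
    D = np.round(D_real).astype(np.int64)
    sizes = np.round(sizes_real).astype(np.int64)
    if sizes.sum() != int(round(N)):
        raise ValueError(
            f"bookkeeping mismatch: class sizes sum to {sizes.sum()} != N={N}"
        )
    k = lh.k
    n1 = int(sizes[0])
    repro = np.flatnonzero(lh.p > 0) + 1
    if np.any(D[repro - 1] < 1):
        raise ValueError("every reproductive class needs at least one spawner")
    rng = np.random.default_rng(seed)
    if quota == "largest_remainder":
        exact = lh.p * n1
        base = np.floor(exact).astype(np.int64)
        rem = n1 - base.sum()
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:rem]] += 1
        quota_counts = base
        class_of_newborn = np.repeat(np.arange(1, k + 1), quota_counts).astype(np.int8)
    elif quota != "multinomial":
        raise ValueError(f"unknown quota mode {quota!r}")
    cum_p = np.cumsum(lh.p)
    # class membership: indices into the birth cohort of each class
    cohorts = [np.arange(sizes[i], dtype=np.int32) for i in range(k)]
    parent_class = np.zeros((years, n1), dtype=np.int8)
    parent_index = np.zeros((years, n1), dtype=np.int32)
    for t in range(years):
        pools = {}
        new_cohorts = [None] * k
        for i in range(k):
            members = cohorts[i]
            perm = rng.permutation(len(members))
            dying = members[perm[: D[i]]]
            if i + 1 in repro:
                pools[i + 1] = dying
            if i + 1 < k:
                new_cohorts[i + 1] = members[perm[D[i] :]]
        if quota == "multinomial":
            cls = (
                np.searchsorted(cum_p, rng.random(n1), side="right") + 1
            ).astype(np.int8)
        else:
            cls = class_of_newborn
        pidx = np.empty(n1, dtype=np.int32)
        for m in repro:
            sel = cls == m
            cnt = int(sel.sum())
            if cnt:
                pidx[sel] = pools[m][rng.integers(0, D[m - 1], size=cnt)]
        parent_class[t] = cls
        parent_index[t] = pidx
        new_cohorts[0] = np.arange(n1, dtype=np.int32)
        cohorts = new_cohorts
        total = sum(len(cc) for cc in cohorts)
        if total != sizes.sum():
            raise RuntimeError(
                f"bookkeeping mismatch at year {t}: population {total} != {sizes.sum()}"
            )
    return ForwardPedigree(
        cohort_size=n1,
        years=years,
        parent_class=parent_class,
        parent_index=parent_index,
        pools=D.astype(float),
        seed=seed,
        settings={"N": float(N), "quota": quota},
    )
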