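"""Demographic bookkeeping for a semelparous age-structured population.

The population of total size ``N`` (all age classes summed) is divided into
``k`` age classes, the first ``n_juvenile`` of which do not reproduce.
Semelparity means every parent dies in the year it spawns, so the parents of
a cohort are found among that year's dead.  Two parameter vectors describe
the demography:

``p``
    ``p[i]`` is the fraction of each newborn cohort parented by age class
    ``i+1`` (1-based age ``i``); zero for juvenile classes and summing to 1.
``c``
    ``c[i]`` is the number of individuals dying in age class ``i+1`` each
    year divided by the total population size ``N``.

Under constant population size and stable age structure the class sizes are
the suffix sums ``N_i = N * sum(c[i-1:])`` and the identity
``sum(i * c_i) == 1`` holds (each individual dies exactly once, at some
age).  Parameter sets used only for the analytic theory need not satisfy the
full bookkeeping identity, so validation has a default (non-strict) mode and
an opt-in strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LifeHistory",
    "validate",
    "from_survival",
    "generation_length",
    "breeders",
]

_SUM_TOL = 1e-12
_STRICT_TOL = 1e-9


@dataclass(frozen=True)
class LifeHistory:
    """Parameter bundle (k age classes, reproductive weights, death fractions).

    Parameters
    ----------
    p : array-like of length k
        Reproductive contribution fractions per age class.
    c : array-like of length k
        Yearly death fractions relative to total size ``N``.
    N : float
        Total population size (sum over all age classes).
    n_juvenile : int
        Number of leading non-reproductive age classes.
    phi : float, optional
        Fraction of the population in the first age class.  Carried as
        metadata only; when the strict bookkeeping holds it is redundant
        with ``sum(c)``.
    """

    p: np.ndarray
    c: np.ndarray
    N: float
    n_juvenile: int = 2
    phi: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))
        if self.p.ndim != 1 or self.c.ndim != 1 or len(self.p) != len(self.c):
            raise ValueError("p and c must be 1-d vectors of equal length")

    # -- derived quantities -------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.p)

    @property
    def ages(self) -> np.ndarray:
        """1-based age of each class."""
        return np.arange(1, self.k + 1)

    @property
    def D(self) -> np.ndarray:
        """Yearly death counts per class, ``D_i = c_i * N``."""
        return self.c * self.N

    @property
    def class_sizes(self) -> np.ndarray:
        """Class sizes ``N_i = N * sum_{j>=i} c_j`` (suffix sums)."""
        return self.N * np.cumsum(self.c[::-1])[::-1]

    @property
    def phi_derived(self) -> float:
        """First-age-class fraction implied by the death fractions."""
        return float(self.c.sum())

    @property
    def reproductive(self) -> np.ndarray:
        """Boolean mask of age classes with nonzero contribution."""
        return self.p > 0

    @property
    def g(self) -> float:
        return generation_length(self)

    @property
    def N_b(self) -> float:
        return breeders(self)

    def sum_p2_over_c(self) -> float:
        """The reproductive-skew sum ``sum_m p_m^2 / c_m`` over spawning classes."""
        m = self.reproductive
        return float(np.sum(self.p[m] ** 2 / self.c[m]))

    def rescaled(self, N: float) -> "LifeHistory":
        """Same demography at a different total size."""
        return replace(self, N=N)


def validate(lh: LifeHistory, strict: bool = False) -> list[str]:
    """Check the life-history invariants; return a list of violation messages.

    An empty list means the input is valid.  ``strict`` additionally requires
    the constant-structure bookkeeping identity ``sum(i * c_i) == 1``
    (equivalent to the class sizes summing to ``N``).  Never mutates ``lh``.
    """
    out: list[str] = []
    p, c = lh.p, lh.c
    if not (0 <= lh.n_juvenile < lh.k):
        out.append(f"n_juvenile must be in [0, k); got {lh.n_juvenile} with k={lh.k}")
        return out
    if lh.N <= 0:
        out.append(f"total size N must be positive; got {lh.N}")
    if np.any(p < 0):
        out.append("contribution fractions p must be non-negative")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        out.append(f"contribution fractions p must sum to 1 (got {p.sum():.15g})")
    if np.any(p[: lh.n_juvenile] > 0):
        out.append("juvenile age classes cannot have p_i > 0")
    if np.any(c < 0):
        out.append("death fractions c must be non-negative")
    bad = (p > 0) & (c <= 0)
    if np.any(bad):
        ages = ", ".join(str(a) for a in lh.ages[bad])
        out.append(
            f"reproductive class with zero deaths (age {ages}): a class cannot "
            "parent newborns if nobody dies/spawns in it"
        )
    sizes = lh.class_sizes
    if np.any(sizes <= 0):
        out.append("derived class sizes N_i must be positive (requires c_k > 0)")
    if np.any(np.diff(sizes) > _SUM_TOL * max(lh.N, 1.0)):
        out.append("derived class sizes N_i must be non-increasing in age")
    if strict:
        total = float(np.dot(lh.ages, c))
        if abs(total - 1.0) > _STRICT_TOL:
            out.append(
                f"strict bookkeeping violated: sum(i * c_i) = {total:.12g} != 1 "
                "(class sizes do not sum to N)"
            )
    return out


def from_survival(
    n_spawners: int,
    eggs_per_spawner: int,
    s: Sequence[float],
    n_juvenile: int = 2,
    p: Sequence[float] | None = None,
    integer: bool = True,
) -> LifeHistory:
    """Build a :class:`LifeHistory` from a fecundity/survival schedule.

    ``s[x-1]`` is the fraction of individuals surviving from the egg pool
    (``x = 1``) or from age class ``x-1`` (``x >= 2``) into age class ``x``.
    The first age class holds ``n_spawners * eggs_per_spawner * s[0]``
    individuals; eggs that die before entering it are not counted in ``N``.
    Each class size is then ``N_x = N_{x-1} * s[x]``, deaths are the
    successive differences (the whole last class dies), and
    ``c_i = D_i / N``.

    With ``integer=True`` (default) class sizes are truncated toward zero,
    matching exact head-count bookkeeping; ``integer=False`` keeps the real
    products for use with the analytic operations.

    ``p`` defaults to the death counts of the reproductive classes,
    normalized — i.e. each spawner contributes equally in expectation
    regardless of age.
    """
    s = np.asarray(s, dtype=float)
    k = len(s)
    if np.any(s <= 0) or np.any(s > 1):
        raise ValueError("survival fractions s must lie in (0, 1]")
    if n_spawners <= 0 or eggs_per_spawner <= 0:
        raise ValueError("spawner and egg counts must be positive")
    sizes = np.empty(k)
    sizes[0] = n_spawners * eggs_per_spawner * s[0]
    for i in range(1, k):
        sizes[i] = sizes[i - 1] * s[i]
    if integer:
        sizes = np.trunc(sizes)
    if sizes[0] < 1:
        raise ValueError("empty cohort: no eggs survive into the first age class")
    D = np.empty(k)
    D[:-1] = sizes[:-1] - sizes[1:]
    D[-1] = sizes[-1]
    N = float(sizes.sum())
    c = D / N
    if p is None:
        p = np.zeros(k)
        pool = D.copy()
        pool[:n_juvenile] = 0.0
        p = pool / pool.sum()
    else:
        p = np.asarray(p, dtype=float)
    return LifeHistory(p=p, c=c, N=N, n_juvenile=n_juvenile)


def generation_length(lh: LifeHistory) -> float:
    """Mean age of parents, ``g = sum_i i * p_i`` (years per generation).

    Equals the reciprocal of the stationary probability that a lineage traced
    backward in time sits in the first age class.
    """
    return float(np.dot(lh.ages, lh.p))


def breeders(lh: LifeHistory) -> float:
    """Yearly effective number of breeders ``N_b = N * sum of adult c_i``.

    In the five-class salmon parameterization this is ``(c_3+c_4+c_5)*N``:
    all adults that die in a year are that year's spawners.
    """
    return float(lh.N * lh.c[lh.n_juvenile:].sum())
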