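"""Random valid life histories for property tests and exploration."""

from __future__ import annotations

import numpy as np

from .life_history import LifeHistory, validate

__all__ = ["generate_fixture"]


def generate_fixture(
    seed: int,
    k: int = 5,
    n_juvenile: int = 2,
    mode: str = "strict",
    balanced: bool = False,
    N: float = 10_000.0,
    max_tries: int = 100_000,
) -> LifeHistory:
    """Draw a random valid :class:`LifeHistory`.

    Reproductive contributions are Dirichlet over the adult classes.  In
    ``"strict"`` mode the death fractions are solved to satisfy the
    bookkeeping identity ``sum(i * c_i) = 1`` with ``c_i > 0`` everywhere;
    in ``"lax"`` mode only the basic invariants are enforced.  With
    ``balanced=True`` the offspring-per-breeder ratios ``p_m / c_m`` of the
    adult classes are kept within a factor 1.5 of each other, mimicking
    roughly equal reproductive variance across age classes.
    """
    if not 0 <= n_juvenile < k:
        raise ValueError("need k > n_juvenile >= 0")
    rng = np.random.default_rng(seed)
    ages = np.arange(1, k + 1, dtype=float)
    n_adult = k - n_juvenile
    for _ in range(max_tries):
        p = np.zeros(k)
        p[n_juvenile:] = rng.dirichlet(np.ones(n_adult))
        if balanced:
            # common offspring-per-breeder ratio, jittered within [1/1.2, 1.2]
            u = rng.uniform(1 / 1.2, 1.2, size=n_adult)
            c_adult = p[n_juvenile:] * u
            if mode == "strict":
                # adult share of the identity sum(i*c_i) = 1
                budget = rng.uniform(0.80, 0.98) if n_juvenile else 1.0
                c_adult *= budget / np.dot(ages[n_juvenile:], c_adult)
                if n_juvenile:
                    w = rng.uniform(0.05, 0.95, size=n_juvenile)
                    w /= np.dot(ages[:n_juvenile], w)
                    c = np.concatenate([(1.0 - budget) * w, c_adult])
                else:
                    c = c_adult
            else:
                c_adult *= rng.uniform(0.2, 0.9) / c_adult.sum()
                c = np.concatenate([rng.uniform(0.01, 0.3, size=n_juvenile), c_adult])
        else:
            c = rng.dirichlet(np.ones(k))
            if mode == "strict":
                c = c / np.dot(ages, c)
            else:
                c = c * rng.uniform(0.3, 1.0)
        lh = LifeHistory(p=p, c=c, N=float(N), n_juvenile=n_juvenile)
        if not validate(lh, strict=(mode == "strict")):
            return lh
    raise RuntimeError(f"no valid fixture found after {max_tries} attempts")
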