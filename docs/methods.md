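# Methods

## The model

We consider a haploid population of constant total size `N` structured into
`k` age classes, the first `n_juvenile` of which do not reproduce (defaults
`k = 5`, `n_juvenile = 2`, the typical Pacific-salmon configuration). Time
advances in years. The demography is stationary: class `i` holds `N_i`
individuals, `D_i` of them die each year (`c_i = D_i / N`), and because the
species is semelparous every adult that reproduces dies in the same season,
so the parent pool of a cohort is exactly that year's dead adults. Newborn
cohorts have size `N_1`; a fraction `p_i` of each cohort is parented by
class `i`, with exchangeable Wright–Fisher (multinomial) offspring counts
within a class: each of the `p_i N_1` class-`i` newborns picks its parent
uniformly among the `D_i` spawners.

Constant size and stable structure tie the quantities together:
`N_i = N * sum_{j>=i} c_j`, `sum_i N_i = N` is equivalent to
`sum_i i * c_i = 1` (every individual dies exactly once, at some age), and
the first-class share `phi = N_1 / N` equals `sum_i c_i`.

Not every parameter set used in practice satisfies the full bookkeeping:
the yearly-series study set (`p = (0,0,.04,.25,.71)`,
`c = (0,0,.01,.05,.15)`, `phi = 0.5`) provably admits no non-negative
juvenile completion with `sum i*c_i = 1` once `phi = 0.5` is imposed. The
analytic operations only need `p`, `c` and `N`, so validation is split into
a default mode (the invariants the theory needs) and an opt-in `strict`
mode (full bookkeeping, required by the forward simulator). `phi` is
carried as metadata only; it enters no formula.

`from_survival` implements the self-consistent cascade
`N_1 = spawners * eggs * s(1)`, `N_i = N_{i-1} * s(i)`; the shipped
chinook example starts from a 200,000-egg pool and reproduces the classic
10,000 / 1,000 / 800 / 640 / 512 head counts exactly. `from_survival` needs a
contribution vector to complete a life history; the default sets `p`
proportional to the adult death counts (each spawner contributes equally in
expectation regardless of age), which is the same "contributions equal
breeder frequencies" convention the series comparison uses. Head counts are
truncated to integers by default; `integer=False` keeps real-valued classes
for analytic work.

## Backward chain and the two-time-scale limit

A single lineage traced backward performs a Markov chain `xi` on age
classes: deterministic aging down one class per year, and from class 1 a
jump to the parent's class (`p_m`). Its stationary law is
`pi_i = (sum_{j>=i} p_j) / g` with `g = sum_i i p_i` the mean parental age;
in particular `pi_1 = 1/g` — one class-1 visit per generation.

Two lineages move as the Kronecker square `xi (x) xi` on the `k^2` ordered
pairs plus an absorbing state `C`, entered from `(1,1)` with probability
`sum_m p_m^2 / D_m`. Writing the exact matrix as `Pi_N = A + B/N + O(1/N^2)`
(the only `O(1/N^2)` term is integer rounding of the pools), the
two-time-scale limit gives the generator `G = P B P` where `P` projects on
the fast process's stationary law: every transient row of `P` is
`pi (x) pi`. The coalescence column of `G` is constant at
`(1/g^2) sum_m p_m^2 / c_m`, hence

```
N_e = N * g / sum_m (p_m^2 / c_m)
```

with mean pair coalescence time `N_e * g` years. Special cases: a single
reproductive class with equal class sizes gives `N_e = N`; the conservative
weighting `p_m = m c_m` gives `N_e = N` because the skew sum telescopes to
`g` (verified symbolically in the tests).

**Periodicity.** The lineage chain is aperiodic iff the reproductive-age
support has gcd 1. With a single reproductive age `k` the chain is a
`k`-cycle: the pair chain preserves the lineages' phase difference, so
out-of-phase pairs never meet in class 1 and never coalesce — the limit
theorem's aperiodicity hypothesis genuinely fails there. The package is
honest about this: `P` is constructed from the stationary (time-average)
law in all cases, but the absorption solver returns `inf` for states that
cannot reach `C`, the pair simulator returns `inf` for phase-mismatched
replicates (probability `1 - 1/k` under stationary sampling), and the
n-lineage simulator refuses periodic inputs. For the synchronized start
`(1,1)` the exact mean is `g * D_k - (g - 1)` years — order `N`, not
`N_e * g`; tests cover this exact value rather than pretending the Kingman
scaling applies.

## Numerical choices

* Finite-`N` chain entries use integer pools `D_m = round(c_m N)` clipped
  to at least 1, keeping `Pi_N` stochastic at small `N`; the analytic `B`
  uses exact `c_m`. The decomposition error `||N(Pi_N - A) - B||_inf` is
  bounded by `sum(p^2/c^2)/N` (pure rounding) and tested at that bound.
* Absorption times solve `(I - T) t = 1` on the transient block by dense
  partial-pivot LU (`k <= 10` keeps everything tiny); unreachable states
  are detected by graph reachability first.
* Stationary laws use the closed form; an eigen-solver serves as the test
  oracle, never the implementation path.
* Tolerances: probability sums to 1 within 1e-12; strict bookkeeping within
  1e-9; generator rows sum to zero within 1e-10; analytic-vs-numeric fast
  limit within 1e-8 at matrix power 4096 for aperiodic chains.

## Simulators

**Backward (pair).** The default engine is event-driven: between class-1
visits a lineage moves deterministically, so each lineage's visit years
form a renewal process with increments distributed as `p`. The engine
advances the lagging lineage; on a shared visit year both draw parental
ages and coalesce with probability `1/D_m` when the ages agree — exactly
the `(1,1)` row of the chain, factored into (class, parent) choices. This
is distributionally identical to stepping the 26-state chain year by year
(the `"chain"` method, kept and compared by a KS test) at a small fraction
of the cost; 20,000 replicates at `N = 5000` take seconds. A single seeded
generator drives all replicates; identical seeds give identical output.

**Backward (n lineages).** Same renewal representation per lineage; in a
shared visit year every visiting lineage draws (class, parent) and lineages
with identical draws merge, so multiple mergers are possible at finite `N`
and replicates containing one are counted. Guard: `n <= 0.01 N`.

**Forward.** Explicit individuals, strict integer bookkeeping (rejected
otherwise, and re-checked every year). Deaths are uniform within class —
the exchangeable choice, since the model does not distinguish juveniles —
and dying adults form the spawner pools. Newborn class quotas are
multinomial by default (matching the model's offspring distribution), with
a deterministic largest-remainder mode as an option. The recorded pedigree
of class-1 cohorts yields two independent checks: the per-year probability
that two random newborns share a parent (`sum p_m^2 / D_m`, a sharp 3-SE
test), and pair TMRCAs traced through the pedigree. Same-cohort pairs start
the backward chain in `(1,1)`, so their oracle is the exact
`(1,1)`-absorption time. Because all pairs of one run share a single
realized genealogy, the mean pairwise TMRCA of one pedigree has a standard
deviation comparable to its mean; the test therefore time-averages over
well-separated cohorts of a 24,000-year run at `N = 500` and uses a
block-based standard error (a fixed-percentage assertion would require
runs orders of magnitude longer).

## Fluctuating size

Yearly sizes are `N x_t` with `x_t` i.i.d. on finitely many atoms
`(x_j, q_j)`; `p`, `c` and the relative class structure stay fixed. The
per-year coalescence probability scales as `1/x`, so averaging over the
size law replaces `N` by the harmonic mean `H = N / sum_j q_j / x_j`:
`N_e = g H / sum_m p_m^2/c_m`. The fluctuating pair simulator redraws `x`
only in shared class-1 visit years (the only years where the size enters),
which is exact under the i.i.d. assumption. Autocorrelated size processes
are out of scope, though any finite-atom sampler could be substituted.

For a yearly breeder series `N_b(t) = (sum adult c_i) * N(t)` the two
classical estimators are `g * harmonic_mean(N_b)` (equal yearly
contributions) and `g * arithmetic_mean(N_b)` (contributions proportional
to breeders). The blockwise comparison cuts the series into
generation-length blocks (default `round(g)` years); the coalescent column
applies the long-term CES formula to each block's empirical size
distribution. There is no canonical per-block convention for a coalescent
"estimate" — this one is a design choice of the package, validated through
the ordering claim (coalescent < harmonic < arithmetic on fluctuating series), which
holds in every block by the strict AM–HM inequality and the fixed ratio
`est_C / est_H = (1 / sum p^2/c) / (sum adult c_i)` (0.998 for the series
preset).

## Synthetic data

`generate_fixture` draws Dirichlet adult contributions and death fractions
rescaled onto `sum i*c_i = 1` (strict mode), optionally balancing
offspring-per-breeder ratios `p_m/c_m` within a factor 1.5 — mimicking
roughly equal reproductive variance across age classes. It emulates
parameter heterogeneity, not data: there is no mutation, no sequence
sampling, no observation noise, so passing tests demonstrate correctness of
the demographic and genealogical machinery, not inference performance on
genetic data.

## Problem sizes

Tests and the acceptance script use: exact matrix work at `N` in
{10^3, 10^4, 10^5} (26-state chains are trivial to solve); backward
Monte-Carlo at `N = 5000` with 20,000 replicates; forward runs at
`N = 500–2000` for 250–24,000 years; five 52-year series replicates for the
estimator comparison. These sizes make every stochastic assertion a 3-SE
test with comfortable margins while keeping the full suite to a few
minutes.

## Known limitations

* Haploid, single panmictic population, no selection, no mutation; diploid
  results would need no major sex differences in age structure or
  reproductive success.
* Sample sizes larger than two are handled by simulation only; the
  `k^n`-state analytic construction is not implemented.
* Reproductive variance is multinomial within classes; high-variance
  (sweepstakes) reproduction would produce multiple-merger genealogies
  outside this framework.
* The expected offspring of a class-`i` adult is `p_i N_1 / D_i` here
  (parents are the dying adults); an alternative reading normalizes by the
  whole class `N_i`. The `D_i` convention is what the coalescence
  probability and all oracles use.
* Size fluctuations must be fast (yearly) and i.i.d.; coalescent-timescale
  size change needs the deterministic-time-change machinery instead.
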