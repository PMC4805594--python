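# Methods

## Model

The package treats well-stirred systems of `M` chemical species whose
state is a count vector `n = (n_1, ..., n_M)` with conserved total
`N = sum n_i` in volume `V`; the total density `rho = N/V` is held fixed
when N is varied, so concentrations are `x_i = n_i rho / N`.  Two event
types drive the dynamics:

* catalytic conversion `i -> k` in the presence of a catalyst `j`, with
  propensity `(rho/N) R_ijk n_i n_j` (rate constant `R_ijk` in units of
  1/(concentration x time));
* non-catalytic conversion `i -> j` (any `j != i`) with propensity
  `(eps/M) n_i` (rate `eps` in 1/time), a weak background channel that
  keeps the chain irreducible when `eps > 0`.

Structural constraints on the catalytic tensor: substrate != catalyst
(`R_iik = 0`), substrate != product (`R_iji = 0`), product != catalyst
(`R_ijj = 0`, no autocatalysis), and one product per (substrate,
catalyst) pair.  The last rule can be relaxed per network
(`allow_multiple_products=True`); one shipped switching fixture uses the
relaxation, and the master equation and simulator remain well defined
there, but the product-form theory is stated for the constrained class.

Autocatalytic systems are handled only through the three shipped
hand-built conversions of the two-species autocatalytic switching (2TK)
model into 4- and 5-species non-autocatalytic networks with aggregate
observables; no general conversion algorithm is attempted.

## Analytical machinery

**Product-form weights.** The stationary PGF ansatz
`(sum_i lambda_i z_i)^N` reduces the stationary condition to linear
equations in the pair products `mu_ij = lambda_i lambda_j` (the pair
matrix).  The solver paths are:

* M = 3 closed form via the invariants
  `Lam_1 = R123 R312 + R132 R213 + R123 R132` (cyclic analogues for
  `Lam_2`, `Lam_3`); all invariants positive gives the nontrivial
  weights, exactly one zero gives a winner-takes-all point, two or more
  zeros leave the weights indefinite (reported as such, no numbers).
* General M: exact null space of the pair matrix (Fraction arithmetic
  when the rates are rational, SVD with relative threshold `1e-10`
  otherwise).  A one-dimensional sign-definite null vector is factorised
  into weights by ratios `lambda_s / lambda_r = mu_st / mu_rt` — exact
  for rational input and sqrt-free — then every pair product is verified
  against `mu` to 1e-9 relative and the full quadratic residual to
  1e-10 (scaled by the largest rate); failure reports "no product
  form" rather than forcing a factorisation.
* Multi-dimensional null spaces are returned as a family: the basis plus
  the factorisable branches found support-by-support.  A support S is
  admissible when no reaction with substrate and catalyst inside S
  produces a species outside S; on each admissible support the quadratic
  system (with weights summing to one) is solved symbolically via sympy,
  and positive branches — parametric or point — are kept.  The
  enumeration covers all `2^M` supports; this is exhaustive for the
  factorisable members but does not parameterise non-factorisable null
  directions beyond the basis.

**Conditioned product form.** Winner-takes-all states are frozen under
catalytic-only dynamics and structurally unreachable (a reaction needs
two distinct species present), so the physical stationary law is the
multinomial with weights `lambda` conditioned away from them.  Its
marginals have three branches (inflated zero atom, truncated binomial
body, exact zero at `n = N`); means, cross moments and variances are
evaluated in exact rational arithmetic when the inputs are rational.
Validity requires *entire ergodicity*; the formula is still computable
for other networks and callers are expected to gate on the ergodicity
check (the CLI does).

**Ergodicity.** Operationalised exactly: build the directed catalytic
transition graph on the enumerated simplex and require the non-WTA
states to form a single strongly connected class with no escape.  For
M = 3 the rate-tensor criterion (every species producible and
consumable) is evaluated alongside and its agreement reported; it is
provably equivalent only at M = 3 — a shipped four-species example
satisfies it yet traps trajectories on an edge.  The state-space cap
defaults to 2e5 states.

**Exact CME oracle.** The generator is assembled as a sparse matrix over
the canonical state order (lexicographically descending tuples, so
distribution vectors are bit-for-bit reproducible).  Stationary
distributions are computed per closed communicating class (classes from
Tarjan-style SCC analysis of the jump graph via networkx): dense SVD
below 2000 states, shift-invert sparse eigensolver above.  A restricted
null space whose dimension is not exactly one raises a diagnostic error
with the singular spectrum instead of returning a silently wrong
vector.

**Moment equations.** The first-moment (pre-rate) equation, the
second-moment expression for time averages (singular at `eps = 0` — the
`eps -> 0` limit of the mixed system differs from the `eps = 0` product
form, a singular perturbation the tests exhibit), and the second-moment
time-evolution equations.  All moments are *raw* product moments of
concentrations; third moments are caller-supplied keyed by sorted index
triples with coincident indices allowed, and no moment-closure scheme is
invented.  The only closure implemented is the exact N = 2 one, where
the third PGF derivatives vanish: the diagonal equation yields
`Var[x_i] = ((M+1) rho/(2M) - xbar_i) xbar_i`, and eliminating the first
moments turns the pair equations into an `M(M-1)/2` linear system
(pair order lexicographic, part of the stable interface) solved exactly
for rational inputs.

**Connecting state.** When a dominant species d is never a substrate and
the weights are definite, the `lambda_d -> 1` limit of the conditioned
product form concentrates on states `n_d = N - 1` with the last molecule
on species i at weight `kappa_i`; the kappa vector is the nonnegative
normalised null vector of a small linear system and is solved exactly.

**Rank analysis.** Orderings are ascending ordered partitions with ties
grouped (never arbitrarily broken); a variance "exchange" is recorded at
N when the partition differs from the one at N - 1.  With exact rational
weights the orderings are exact, so the change points are integers, not
tolerance artefacts.

## Simulator

Gillespie direct method: two uniforms per event from numpy's PCG64
generator, exponential waiting times, categorical event choice; the seed
is stored on every trajectory.  The non-catalytic self-conversion
`j = i` is a statistical no-op and is excluded from the event list.
Time averages weight states by occupancy time (not per event); a frozen
trajectory contributes its terminal state as a point mass, since the
process spends unbounded time there.  Default burn-in in the CLI is 10%
of the requested reactions.  No tau-leaping or other acceleration: exact
SSA only, adequate at the package's target sizes.

Initial conditions "uniform over non-WTA states" are sampled by
stars-and-bars with rejection of WTA draws; by symmetry the per-species
mean is N/M.

## Test and validation sizes

Analytical assertions are exact or at 1e-10; stochastic validation is
scaled to desk size: 1e6 reactions with 1e5 burn-in for the
three-species marginal comparison (total-variation tolerance 0.02),
2e6 reactions for the five-species switching aggregate at N = 20 and
1e6 at N = 500 with 10% burn-in.  At these sizes the bimodal (N = 20)
versus unimodal (N = 500) shapes of the aggregate occupancy histogram
are resolved with a wide margin across seeds (middle-quintile occupancy
~0.17 vs outer-quintile ~0.20+ at N = 20, and ~0.77 vs ~0.1 reversed at
N = 500).

## What the fixtures do and do not show

The shipped networks are minimal mathematical examples (unit or simple
rational rates, 3-5 species).  Passing tests demonstrate the internal
consistency of the formulas, the exact solver and the simulator on this
class; they do not establish that any real biochemical pathway is
well-approximated by two-body catalysis with a uniform non-catalytic
channel, nor do they probe rate heterogeneity over orders of magnitude
beyond the `1997/3 : 1` asymmetry of `triangle_c`.

## Known limitations

* Exact solvers enumerate the state space; memory and the 2e5-state cap
  bound N and M (M = 5, N = 55 is near the cap).  The simulator has no
  such limit.
* The product-form approximation for small `eps > 0` on entirely
  ergodic networks is checked empirically (simulation comparisons), not
  proved.
* Family extraction relies on sympy's solver for the per-support
  quadratic systems; for M well beyond 5 both the `2^M` support loop and
  the symbolic solves would need rework.
* Non-catalytic-only results assume every species participates; species
  absent from all reactions still equilibrate via the `eps` channel.
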