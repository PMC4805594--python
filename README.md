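# catnet

Analytical steady states and stochastic simulation of **small-number
catalytic reaction networks** — systems of M chemical species and a
conserved total of N molecules in which every conversion `i -> k` is
driven by a catalyst `j` at rate constant `R_ijk`, plus a weak
non-catalytic channel `i -> j` at rate `eps/M` per molecule.  When N is
small (a handful of molecules, as for rare transcription factors or
scaffold proteins in a cell) the deterministic rate equations fail and
the system must be described by the chemical master equation (CME) over
the discrete simplex `W = {n >= 0 : n_1 + ... + n_M = N}`.

The package is for modellers who want the *exact* stationary behaviour
of such networks without brute-force simulation: the product-form
stationary solution of the CME, its small-N moments, the associated
rank laws, and cross-validating exact and stochastic solvers.

## The theory in brief

For purely catalytic dynamics the stationary probability generating
function is sought as `phi(z) = (sum_i lambda_i z_i)^N` with weights
`lambda_i >= 0`, `sum_i lambda_i = 1`.  Substituting into the stationary
generating-function equation gives a homogeneous quadratic condition
that is *linear* in the pair products `lambda_i lambda_j`:

```
sum_k [ R_kij l_k l_i + R_kji l_k l_j - (R_ijk + R_jik) l_i l_j ] = 0,   i < j
```

so the weights come from the null space of an `M(M-1)/2` "pair matrix"
plus a rank-one factorisation.  For M = 3 a closed form exists via three
invariants `Lam_i` built from the rates.  Because the winner-takes-all
(WTA) states — one species holding all N molecules — are frozen and
unreachable, the physical stationary distribution is the multinomial
*conditioned away from WTA*:

```
P(n) = multinomial(N; n) prod_i lambda_i^{n_i} / (1 - sum_i lambda_i^N)   (n not WTA)
```

with closed-form marginals, means `xbar_i = rho (l_i - l_i^N)/(1 - sum l^N)`
and variances.  Consequences implemented here:

* **Rank conservation** — the ordering of the mean concentrations equals
  the ordering of the weights for *every* N >= 2, while the ordering of
  the variances can exchange as N changes.
* **Connecting state to the WTA state** — when one species is never a
  substrate, the limit `lambda_1 -> 1` survives as a stationary state
  concentrated on `n_1 = N - 1` with the roaming molecule distributed by
  linear-condition weights `kappa_i`.
* **Two-molecule systems (N = 2)** — the second-moment dynamics close
  exactly: `Var[x_i] = ((M+1) rho/(2M) - xbar_i) xbar_i`, and the pair
  moments of the mixed (eps > 0) system solve a small linear system that
  back-substitutes into the concentrations.
* **Entire ergodicity** — the product form applies when a single
  catalytic-only trajectory can visit all non-WTA states; decided
  exactly by strong-connectivity analysis of the transition graph, with
  the M = 3 rate-tensor criterion checked alongside.

Everything is cross-validated against a brute-force oracle (null space
of the sparse CME generator) and a seeded Gillespie direct-method
simulator.  Exact rational arithmetic is used end to end whenever the
rates are rational, so printed fractions such as `2/11` are reproduced
bit-exactly.

## Worked example

Seven example networks ship with the package (`catnet fixtures list`).
The three-species network `triangle_a` (five unit-rate reactions, one
link removed):

```sh
catnet analyze --fixture triangle_a --N 10 --no-oracle
```

prints (abridged):

```json
{
 "lambda": ["2/11", "3/11", "6/11"],
 "ergodicity": {"verdict": "entirely_ergodic"},
 "product_form": {
  "xbar": {"1": 0.1822434162645893, "2": 0.27336290183530726, "3": 0.5443936819001035},
  "var":  {"1": 0.014833299649511945, "2": 0.01970568727776882, "3": 0.024366777935204142}
 }
}
```

The weights `(2/11, 3/11, 6/11)` are the exact infinite-N concentration
fractions; at N = 10 the conditioning away from WTA states shifts the
means slightly off `lambda_i` (0.182 vs 0.1818...), and the variances
are O(1/N) — the small-number correction the theory quantifies.  The
same numbers are recovered by the exact CME null space (`--oracle`) and,
statistically, by the simulator (`catnet simulate`).

In Python:

```python
import catnet as cn
from fractions import Fraction

net = cn.get_fixture("triangle_a").network
sol = cn.solve_lambda_M3(net)        # exact: (2/11, 3/11, 6/11)
mom = cn.pgfwowtas_moments(sol.lambdas, N=10, rho=1)
rep = cn.ergodicity_check(net, N=10) # verdict: entirely ergodic
```

## Layout

| module | contents |
| --- | --- |
| `catnet.network` | network validation, state-space enumeration, winner-set classification, JSON/TSV I/O |
| `catnet.cme` | sparse CME generator, exact stationary distributions, moments/marginals, ergodicity graph check |
| `catnet.steady` | pair matrix, closed-form and general weight solvers, weight families, conditioned product form, connecting state, rank analysis |
| `catnet.moments` | first/second moment evolution equations, time-average expressions, N = 2 closures and the pair-moment linear system |
| `catnet.gillespie` | direct-method SSA, time averages, aggregated observables |
| `catnet.fixtures` | built-in networks, 2TK switching-model conversions, random network generator |
| `catnet.cli` | `catnet validate / analyze / simulate / sweep / fixtures` |

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.
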