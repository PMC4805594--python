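"""Product-form steady states of the catalytic-only dynamics.

The stationary PGF of a purely catalytic network is sought as a power of
a linear form, (sum_i lambda_i z_i)^N.  The weights lambda_i (summing to
one) must satisfy a homogeneous quadratic condition which is *linear* in
the pair products lambda_i lambda_j, so the whole problem reduces to the
null space of an M(M-1)/2-dimensional "pair matrix" plus a rank-one
factorisation step.  Conditioning the resulting multinomial away from
the frozen winner-takes-all states gives the product-form stationary
distribution, its marginals and its concentration moments.

Special structure handled here:

* For M = 3 a closed form exists: three pairwise-product invariants
  (Lam_1, Lam_2, Lam_3) built from the rates give the weights directly;
  one vanishing invariant flags a winner-takes-all solution and two flag
  an indefinite case.
* When the dominant species is never a substrate, the one-lambda-to-one
  limit of the product form survives as the "connecting state" to the
  winner-takes-all state: all mass sits on states with N-1 molecules of
  the dominant species, split among the others by weights kappa_i that
  solve a linear condition.
* Multi-dimensional pair-matrix null spaces are reported as families;
  the factorisable members are extracted support-by-support.

Concentration ranks: the ordering of the time-averaged concentrations
equals the ordering of the lambda weights for every N >= 2 (rank
conservation), while variance orderings may exchange as N grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational

import numpy as np
import sympy

from ._linalg import all_rational, format_rate, nullspace
from .cme import Distribution
from .moments import MomentSet
from .network import ReactionNetwork, StateSpace, enumerate_states

__all__ = [
    "LambdaSolution",
    "LambdaFamily",
    "ProductFormFamily",
    "KappaSolution",
    "lambda_pair_matrix",
    "solve_lambda_M3",
    "solve_lambda_general",
    "extract_product_families",
    "pgfwowtas_distribution",
    "pgfwowtas_marginal",
    "pgfwowtas_moments",
    "noncatalytic_stationary",
    "kappa_solve",
    "cstowtas",
    "rank_analysis",
    "RankReport",
]

RESIDUAL_TOL = 1e-10


def pair_order(M: int):
    """Lexicographic ordering of unordered species pairs (1,2),(1,3),..."""
    return [(i, j) for i in range(1, M + 1) for j in range(i + 1, M + 1)]


def lambda_pair_matrix(network: ReactionNetwork):
    """Matrix A of the pair-product condition, A (lam_i lam_j)_{i<j} = 0.

    Row (i, j) states that the net probability flux between species i
    and j vanishes: each reaction (substrate a, catalyst b, product c)
    contributes +R to row (b, c) at column (a, b) and -R to the diagonal
    of row (a, b).  Returns ``(rows, pairs)``; exact Fractions whenever
    the rates are rational.
    """
    M = network.M
    pairs = pair_order(M)
    pos = {p: i for i, p in enumerate(pairs)}
    exact = network.is_rational
    zero = Fraction(0) if exact else 0.0
    A = [[zero for _ in pairs] for _ in pairs]
    for (a, b, c), R in network.reactions.items():
        R = Fraction(R) if exact else float(R)
        A[pos[(min(b, c), max(b, c))]][pos[(min(a, b), max(a, b))]] += R
        A[pos[(min(a, b), max(a, b))]][pos[(min(a, b), max(a, b))]] -= R
    return A, pairs


def lambda_residual(network: ReactionNetwork, lambdas) -> float:
    """Max residual of the pair-product condition, scaled by the max rate."""
    A, pairs = lambda_pair_matrix(network)
    mu = [lambdas[i - 1] * lambdas[j - 1] for i, j in pairs]
    res = max(
        (abs(float(sum(a * m for a, m in zip(row, mu)))) for row in A),
        default=0.0,
    )
    scale = max((float(R) for R in network.reactions.values()), default=1.0)
    return res / scale


@dataclass
class LambdaSolution:
    """Product-form weights with classification and residual.

    classification is one of ``nontrivial`` (all weights < 1),
    ``trivial_WTA`` (a winner-takes-all point mass), ``indefinite`` (the
    closed form degenerates), or ``no_product_form``.
    """

    lambdas: tuple | None
    classification: str
    residual: float = 0.0
    Lambdas: tuple | None = None  # M = 3 intermediate invariants
    exact: bool = False

    @property
    def is_nontrivial(self) -> bool:
        return self.classification == "nontrivial"

    def to_dict(self):
        return {
            "classification": self.classification,
            "lambda": None
            if self.lambdas is None
            else [format_rate(v) if isinstance(v, Fraction) else float(v)
                  for v in self.lambdas],
            "residual": self.residual,
            "Lambda_invariants": None
            if self.Lambdas is None
            else [format_rate(v) if isinstance(v, Fraction) else float(v)
                  for v in self.Lambdas],
        }


def solve_lambda_M3(network: ReactionNetwork) -> LambdaSolution:
    """Closed-form weights for three-species networks.

    Lam_1 = R123 R312 + R132 R213 + R123 R132 (and cyclic analogues);
    lam_1 = Lam_2 Lam_3 / (Lam_1 Lam_2 + Lam_1 Lam_3 + Lam_2 Lam_3).
    Exactly one vanishing invariant Lam_i yields the trivial solution
    e_i; two or more leave the weights indefinite.
    """
    if network.M != 3:
        raise ValueError("closed form applies to M = 3 only")
    R = network.rate
    exact = network.is_rational
    L1 = R(1, 2, 3) * R(3, 1, 2) + R(1, 3, 2) * R(2, 1, 3) + R(1, 2, 3) * R(1, 3, 2)
    L2 = R(2, 1, 3) * R(3, 2, 1) + R(2, 3, 1) * R(1, 2, 3) + R(2, 1, 3) * R(2, 3, 1)
    L3 = R(3, 1, 2) * R(2, 3, 1) + R(3, 2, 1) * R(1, 3, 2) + R(3, 1, 2) * R(3, 2, 1)
    Lam = (L1, L2, L3)
    zeros = [i for i, L in enumerate(Lam) if L == 0]
    if len(zeros) >= 2:
        return LambdaSolution(
            lambdas=None, classification="indefinite", Lambdas=Lam, exact=exact
        )
    if len(zeros) == 1:
        lam = [0, 0, 0]
        lam[zeros[0]] = 1
        if exact:
            lam = [Fraction(v) for v in lam]
        return LambdaSolution(
            lambdas=tuple(lam),
            classification="trivial_WTA",
            Lambdas=Lam,
            exact=exact,
        )
    S = L1 * L2 + L1 * L3 + L2 * L3
    lam = (L2 * L3 / S, L1 * L3 / S, L1 * L2 / S)
    if exact:
        lam = tuple(Fraction(v) for v in lam)
    sol = LambdaSolution(
        lambdas=lam, classification="nontrivial", Lambdas=Lam, exact=exact
    )
    sol.residual = lambda_residual(network, lam)
    return sol


@dataclass
class ProductFormFamily:
    """A factorisable branch of the pair-matrix null cone.

    ``support`` lists the species with positive weight; ``exprs`` gives
    each species' weight as a sympy expression in the free parameters
    (constrained so the weights sum to one).  A zero-dimensional branch
    (no free parameters) is a single product-form solution.
    """

    support: tuple
    exprs: dict
    params: tuple
    M: int = 0

    @property
    def dimension(self) -> int:
        return len(self.params)

    def sample(self, value=Fraction(1, 4)):
        """Evaluate the branch at one parameter point (default 1/4).

        Returns a full-length tuple of weights (zeros off the support).
        """
        subs = {p: sympy.Rational(value) for p in self.params}
        M = self.M or max(self.support)
        out = []
        for s in range(1, M + 1):
            e = self.exprs.get(s, sympy.Integer(0))
            out.append(Fraction(str(sympy.nsimplify(e.subs(subs)))))
        return tuple(out)

    def matches(self, lambdas, tol=1e-9) -> bool:
        """Does a concrete weight vector lie on this branch?"""
        lam = list(lambdas)
        support = tuple(i + 1 for i, v in enumerate(lam) if v != 0)
        if support != self.support:
            return False
        syms = list(self.params)
        if not syms:
            ref = self.sample()
            return all(
                abs(float(a) - float(b)) <= tol for a, b in zip(ref, lam)
            )
        # solve for the parameters from one coordinate, then verify all
        eqs = [
            sympy.Eq(self.exprs.get(s, sympy.Integer(0)), sympy.Rational(
                Fraction(lam[s - 1]) if isinstance(lam[s - 1], Rational)
                else sympy.nsimplify(lam[s - 1], rational=True)
            ))
            for s in range(1, (self.M or max(self.support)) + 1)
        ]
        sols = sympy.solve(eqs, syms, dict=True)
        return bool(sols)


@dataclass
class LambdaFamily:
    """Null space of the pair matrix with its factorisable branches."""

    basis: list  # null-space basis over pair coordinates
    pairs: list
    families: list  # ProductFormFamily branches

    @property
    def dimension(self) -> int:
        return len(self.basis)

    def find(self, support) -> ProductFormFamily | None:
        support = tuple(sorted(support))
        for fam in self.families:
            if fam.support == support:
                return fam
        return None


def _factor_pair_vector(mu, pairs, M):
    """Rank-one factorisation of a nonnegative pair-product vector.

    Given mu_{ij} ~ lam_i lam_j, recover lam up to scale through ratios
    (exact for rational input), verify every pair product, and normalise
    to sum one.  Returns None when the vector is not factorisable.
    """
    vals = dict(zip(pairs, mu))
    support = sorted(
        {i for (i, j), v in vals.items() if v > 0}
        | {j for (i, j), v in vals.items() if v > 0}
    )
    if len(support) < 3:
        return None  # a single positive pair is a family, not a point
    r = support[0]
    lam = {r: 1 if isinstance(mu[0], Rational) else 1.0}
    for s in support[1:]:
        t = next(
            (
                t
                for t in support
                if t not in (r, s)
                and vals[(min(s, t), max(s, t))] > 0
                and vals[(min(r, t), max(r, t))] > 0
            ),
            None,
        )
        if t is None:
            return None
        lam[s] = vals[(min(s, t), max(s, t))] / vals[(min(r, t), max(r, t))]
    # a vanishing pair product between two supported species is fatal
    if any(
        v == 0 and i in lam and j in lam for (i, j), v in vals.items()
    ):
        return None
    # verify all pair products agree with mu up to one common scale
    scales = [lam[i] * lam[j] / v for (i, j), v in vals.items() if v > 0]
    ref = scales[0]
    for s in scales[1:]:
        if abs(float(s / ref) - 1.0) > 1e-9:
            return None
    total = sum(lam.values())
    return tuple(
        (lam.get(s, 0) / total) if s in lam else (0 * total) for s in
        range(1, M + 1)
    )


def extract_product_families(network: ReactionNetwork) -> list:
    """Factorisable product-form branches, enumerated support by support.

    A support S is admissible when no reaction with substrate and
    catalyst in S produces a species outside S (otherwise weight leaks
    out of S).  On each admissible support the pair-product condition is
    solved symbolically with the weights constrained to sum to one;
    positive-weight branches are returned, parametric ones included.
    """
    M = network.M
    branches = []
    for mask in range(1, 1 << M):
        support = tuple(s for s in range(1, M + 1) if mask >> (s - 1) & 1)
        if len(support) < 2:
            continue
        sset = set(support)
        leaks = any(
            a in sset and b in sset and c not in sset
            for (a, b, c) in network.reactions
        )
        if leaks:
            continue
        syms = {s: sympy.Symbol(f"lam{s}", positive=True) for s in support}
        eqs = []
        for ii, i in enumerate(support):
            for j in support[ii + 1:]:
                expr = sympy.Integer(0)
                for (a, b, c), R in network.reactions.items():
                    Rs = sympy.Rational(R) if isinstance(R, Rational) else R
                    if b == i and c == j and a in sset:
                        expr += Rs * syms[a] * syms[i]
                    if b == j and c == i and a in sset:
                        expr += Rs * syms[a] * syms[j]
                    if (a, b) in ((i, j), (j, i)):
                        expr -= Rs * syms[i] * syms[j]
                eqs.append(expr)
        eqs.append(sum(syms.values()) - 1)
        sols = sympy.solve(eqs, list(syms.values()), dict=True)
        for sol in sols:
            exprs = {s: sympy.simplify(sol.get(syms[s], syms[s]))
                     for s in support}
            free = sorted(
                {
                    sym
                    for e in exprs.values()
                    for sym in e.free_symbols
                },
                key=str,
            )
            # reject branches that force some supported weight to zero or
            # cannot be positive
            if any(e == 0 for e in exprs.values()):
                continue
            if not free and any(
                not (0 < sympy.Rational(e) < 1) for e in exprs.values()
            ):
                continue
            branches.append(
                ProductFormFamily(
                    support=support, exprs=exprs, params=tuple(free), M=M
                )
            )
    return branches


def solve_lambda_general(network: ReactionNetwork):
    """Weights for arbitrary M via the pair-matrix null space.

    One-dimensional sign-definite null spaces are factorised into a
    single weight vector; anything else is returned as a LambdaFamily
    carrying the basis and the factorisable branches.
    """
    A, pairs = lambda_pair_matrix(network)
    basis = nullspace(A, ncols=len(pairs))
    if len(basis) == 0:
        return LambdaSolution(
            lambdas=None, classification="no_product_form",
            exact=network.is_rational,
        )
    if len(basis) == 1:
        v = list(basis[0])
        if all(x <= 0 for x in v):
            v = [-x for x in v]
        if all(x >= 0 for x in v):
            lam = _factor_pair_vector(v, pairs, network.M)
            if lam is not None:
                sol = LambdaSolution(
                    lambdas=lam,
                    classification="nontrivial",
                    exact=all_rational(lam),
                )
                sol.residual = lambda_residual(network, lam)
                if sol.residual > RESIDUAL_TOL:
                    return LambdaSolution(
                        lambdas=None, classification="no_product_form",
                        residual=sol.residual,
                    )
                return sol
        # fall through: a single null direction that is a pair family
        # (two-species support) or not factorisable
    return LambdaFamily(
        basis=basis, pairs=pairs,
        families=extract_product_families(network),
    )


# ---------------------------------------------------------------------------
# distributions, marginals, moments of the product form without WTA states


def _check_nontrivial(lambdas):
    lam = list(lambdas)
    if any(v >= 1 for v in lam):
        raise ValueError(
            "a weight equals one (winner-takes-all): the conditioned "
            "product form does not exist; analyse the connecting state "
            "to the winner-takes-all state instead"
        )
    if abs(float(sum(lam)) - 1.0) > 1e-12:
        raise ValueError("weights must sum to one")
    return lam


def pgfwowtas_distribution(
    lambdas, N: int, space: StateSpace | None = None
) -> Distribution:
    """Multinomial conditioned away from winner-takes-all states.

    P(n) = multinomial(N; n) prod_i lam_i^{n_i} / (1 - sum_i lam_i^N)
    off the WTA states, exactly zero on them.
    """
    lam = _check_nontrivial(lambdas)
    M = len(lam)
    if space is None:
        space = enumerate_states(M, N)
    exact = all_rational(lam)
    denom = 1 - sum(v**N for v in lam)
    p = np.zeros(len(space))
    for idx, state in enumerate(space.states):
        if max(state) == N:
            continue
        coeff = math.factorial(N)
        for c in state:
            coeff //= math.factorial(c)
        w = Fraction(coeff) if exact else float(coeff)
        for v, c in zip(lam, state):
            if c:
                w *= v**c
        p[idx] = float(w / denom)
    return Distribution(
        space, p, source="analytic", context={"lambdas": tuple(lam), "N": N}
    )


def pgfwowtas_marginal(lambdas, species: int, N: int) -> np.ndarray:
    """Marginal of one species under the conditioned product form.

    Three branches: an inflated atom at zero (absorbing the excluded
    WTA mass of the other species), a truncated binomial body, and an
    exact zero at n = N.
    """
    lam = _check_nontrivial(lambdas)
    li = lam[species - 1]
    denom = 1 - sum(v**N for v in lam)
    out = np.zeros(N + 1)
    out[0] = float(
        ((1 - li) ** N + li**N - sum(v**N for v in lam)) / denom
    )
    for n in range(1, N):
        out[n] = float(
            math.comb(N, n) * li**n * (1 - li) ** (N - n) / denom
        )
    out[N] = 0.0
    return out


def pgfwowtas_moments(lambdas, N: int, rho) -> MomentSet:
    """Concentration moments of the conditioned product form.

    xbar_i = rho (lam_i - lam_i^N) / (1 - sum lam^N); cross moments and
    variances follow from the second PGF derivatives.  As N grows the
    means tend to lam_i rho and the variances to zero.  Exact rational
    arithmetic is preserved when the weights and rho are rational.
    """
    lam = _check_nontrivial(lambdas)
    M = len(lam)
    denom = 1 - sum(v**N for v in lam)
    first = {
        i + 1: rho * (lam[i] - lam[i] ** N) / denom for i in range(M)
    }
    exact = all_rational(lam) and isinstance(rho, Rational)
    one_less = (1 - Fraction(1, N)) if exact else (1.0 - 1.0 / N)
    cross = {
        (i + 1, j + 1): rho * rho * one_less * lam[i] * lam[j] / denom
        for i in range(M)
        for j in range(i + 1, M)
    }
    invN = Fraction(1, N) if exact else 1.0 / N
    diag = {
        i + 1: rho
        * rho
        * (lam[i] ** 2 - lam[i] ** N - invN * lam[i] * (lam[i] - 1))
        / denom
        for i in range(M)
    }
    return MomentSet(
        first=first,
        second_cross=cross,
        second_diag=diag,
        context={"N": N, "rho": rho, "epsilon": 0, "M": M},
    )


def noncatalytic_stationary(M: int, N: int, rho):
    """Stationary state when only the non-catalytic channel acts.

    The distribution is multinomial with uniform weights 1/M over the
    whole simplex (WTA states included), each marginal is binomial
    (N, 1/M), and Var[x_i] = (rho/M)^2 (M-1)/N.
    Returns (distribution, marginals list, moments).
    """
    space = enumerate_states(M, N)
    p = np.zeros(len(space))
    for idx, state in enumerate(space.states):
        coeff = math.factorial(N)
        for c in state:
            coeff //= math.factorial(c)
        p[idx] = coeff / M**N
    dist = Distribution(
        space, p, source="analytic", context={"N": N, "M": M, "kind": "nc"}
    )
    marg = np.array(
        [
            math.comb(N, n) * (1 / M) ** n * (1 - 1 / M) ** (N - n)
            for n in range(N + 1)
        ]
    )
    exact = isinstance(rho, Rational)
    um = Fraction(rho, M) if exact else rho / M
    one_less = (1 - Fraction(1, N)) if exact else (1.0 - 1.0 / N)
    var = um * um * (M - 1) * (Fraction(1, N) if exact else 1.0 / N)
    moments = MomentSet(
        first={i: um for i in range(1, M + 1)},
        second_cross={
            (i, j): um * um * one_less
            for i in range(1, M + 1)
            for j in range(i + 1, M + 1)
        },
        second_diag={i: var + um * um for i in range(1, M + 1)},
        context={"N": N, "rho": rho, "M": M, "epsilon": None},
    )
    return dist, [marg] * M, moments


# ---------------------------------------------------------------------------
# connecting state to the winner-takes-all state


@dataclass
class KappaSolution:
    """Weights of the connecting state to the winner-takes-all state."""

    dominant: int
    kappa: dict  # species (!= dominant) -> weight
    residual: float
    lambda_definite: bool | None = None
    exact: bool = False

    def to_dict(self):
        return {
            "dominant": self.dominant,
            "kappa": {
                str(i): format_rate(v) if isinstance(v, Fraction) else float(v)
                for i, v in sorted(self.kappa.items())
            },
            "residual": self.residual,
            "lambda_definite": self.lambda_definite,
        }


def kappa_solve(network: ReactionNetwork, dominant: int) -> KappaSolution:
    """Solve the linear condition for the connecting-state weights.

    Requires the dominant species never to appear as a substrate (it
    must hold N-1 molecules indefinitely); the weights kappa_i then
    balance the fluxes of the single roaming molecule, catalysed by the
    dominant species: sum_k (kappa_k R_{k,d,j} - kappa_j R_{j,d,k}) = 0.
    """
    M = network.M
    d = dominant
    offenders = [t for t in network.reactions if t[0] == d]
    if offenders:
        raise ValueError(
            f"species {d} appears as a substrate in {offenders}; no "
            "connecting state to its winner-takes-all state exists"
        )
    others = [s for s in range(1, M + 1) if s != d]
    exact = network.is_rational
    zero = Fraction(0) if exact else 0.0
    pos = {s: i for i, s in enumerate(others)}
    B = [[zero for _ in others] for _ in others]
    for j in others:
        for k in others:
            Rk = network.rate(k, d, j)
            if Rk:
                B[pos[j]][pos[k]] += Rk
            Rj = network.rate(j, d, k)
            if Rj:
                B[pos[j]][pos[j]] -= Rj
    basis = nullspace(B, ncols=len(others))
    candidates = []
    for v in basis:
        if all(x <= 0 for x in v):
            v = [-x for x in v]
        if all(x >= 0 for x in v) and sum(v) > 0:
            candidates.append(v)
    if not candidates:
        raise ValueError(
            "no nonnegative normalised weight vector solves the "
            "connecting-state condition"
        )
    v = candidates[0]
    total = sum(v)
    kappa = {s: v[pos[s]] / total for s in others}
    residual = max(
        abs(
            float(
                sum(
                    kappa[k] * network.rate(k, d, j)
                    - kappa[j] * network.rate(j, d, k)
                    for k in others
                )
            )
        )
        for j in others
    )
    definite = None
    if M == 3:
        definite = solve_lambda_M3(network).classification != "indefinite"
    return KappaSolution(
        dominant=d,
        kappa=kappa,
        residual=residual,
        lambda_definite=definite,
        exact=exact,
    )


def cstowtas(kappa: KappaSolution, N: int, rho):
    """Distribution, marginals and moments of the connecting state.

    All probability sits on states with N-1 molecules of the dominant
    species and the last molecule on species i with weight kappa_i.
    Returns (distribution, marginals dict, moments).
    """
    M = len(kappa.kappa) + 1
    d = kappa.dominant
    space = enumerate_states(M, N)
    p = np.zeros(len(space))
    for s, w in kappa.kappa.items():
        state = [0] * M
        state[d - 1] = N - 1
        state[s - 1] = 1
        p[space.index[tuple(state)]] = float(w)
    dist = Distribution(
        space, p, source="analytic",
        context={"kappa": dict(kappa.kappa), "dominant": d, "N": N},
    )
    marginals = {}
    md = np.zeros(N + 1)
    md[N - 1] = 1.0
    marginals[d] = md
    for s, w in kappa.kappa.items():
        m = np.zeros(N + 1)
        m[0] = 1.0 - float(w)
        m[1] = float(w)
        marginals[s] = m
    exact = kappa.exact and isinstance(rho, Rational)
    invN = Fraction(1, N) if exact else 1.0 / N
    first = {d: rho * (1 - invN)}
    diag = {d: rho * rho * (1 - invN) ** 2}
    cross = {}
    for s, w in kappa.kappa.items():
        first[s] = rho * w * invN
        diag[s] = rho * rho * w * invN * invN
    for i in range(1, M + 1):
        for j in range(i + 1, M + 1):
            if d in (i, j):
                other = j if i == d else i
                cross[(i, j)] = (
                    rho * rho * kappa.kappa[other] * (N - 1) * invN * invN
                )
            else:
                cross[(i, j)] = 0 * rho
    moments = MomentSet(
        first=first, second_cross=cross, second_diag=diag,
        context={"N": N, "rho": rho, "M": M, "epsilon": 0},
    )
    return dist, marginals, moments


# ---------------------------------------------------------------------------
# rank analysis


def _ordered_partition(values):
    """Ascending ordering of species by value, ties grouped.

    Returns a tuple of tuples of 1-based species indices.
    """
    items = sorted(values.items(), key=lambda kv: kv[1])
    groups = []
    for sp, val in items:
        if groups and values[groups[-1][-1]] == val:
            groups[-1].append(sp)
        else:
            groups.append([sp])
    return tuple(tuple(g) for g in groups)


@dataclass
class RankReport:
    """Concentration and variance orderings across a range of N."""

    N_values: list
    lambda_ordering: tuple
    conc_orderings: dict
    var_orderings: dict
    conc_rank_conserved: bool
    variance_exchanges: list = field(default_factory=list)


def rank_analysis(lambdas, rho, N_range) -> RankReport:
    """Scan the moment formulas over N and track orderings.

    The concentration ordering must match the ordering of the weights at
    every N (rank conservation); the variance ordering is compared
    between consecutive N and every change point is recorded ("exchange
    between N and N+1" appears as the entry N+1).
    """
    lam = list(lambdas)
    M = len(lam)
    lam_order = _ordered_partition({i + 1: lam[i] for i in range(M)})
    Ns = sorted(N_range)
    conc_orderings, var_orderings = {}, {}
    conserved = True
    exchanges = []
    prev_var = None
    for N in Ns:
        mom = pgfwowtas_moments(lam, N, rho)
        co = _ordered_partition(mom.first)
        vo = _ordered_partition({i: mom.var(i) for i in mom.first})
        conc_orderings[N] = co
        var_orderings[N] = vo
        if co != lam_order:
            conserved = False
        if prev_var is not None and vo != prev_var:
            exchanges.append(N)
        prev_var = vo
    return RankReport(
        N_values=Ns,
        lambda_ordering=lam_order,
        conc_orderings=conc_orderings,
        var_orderings=var_orderings,
        conc_rank_conserved=conserved,
        variance_exchanges=exchanges,
    )
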