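"""Moment relations derived from the generating-function equation.

All quantities are concentration moments: x_i = n_i rho / N.  Second
moments <x_i x_j> are raw product moments; third moments (needed by the
time-evolution equations for N > 2) are raw moments too, keyed by sorted
index triples with coincident indices allowed.

The relations implemented here:

* PRE  — time evolution of the first moments, driven by second moments;
  summing over species reproduces the concentration conservation law.
* SME  — steady-state expression of the time-averaged concentrations in
  terms of the time-averaged second moments; singular at eps = 0.
* TESM — time evolution of the second moments, driven by third moments
  (not closed in general).
* 2-molecule closure — at N = 2 the third PGF derivatives vanish, so
  the second-moment dynamics close: the variance of each species is a
  function of its own mean alone, and the cross moments satisfy an
  M(M-1)/2-dimensional linear system (solved exactly when the rates and
  eps are rational), whose solution back-substituted into the SME gives
  the concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational

from ._linalg import all_rational, solve_linear
from .network import ReactionNetwork

__all__ = [
    "MomentSet",
    "pre_rhs",
    "sme_concentrations",
    "tesm_rhs",
    "two_mol_variance_relation",
    "build_2mdesm",
    "solve_2mdesm",
    "two_molecule_steady",
]


@dataclass
class MomentSet:
    """First and second (optionally third) concentration moments."""

    first: dict
    second_cross: dict
    second_diag: dict
    third: dict | None = None
    context: dict = field(default_factory=dict)

    def second(self, i: int, j: int):
        if i == j:
            return self.second_diag[i]
        return self.second_cross[(min(i, j), max(i, j))]

    def third_moment(self, i: int, j: int, k: int):
        if self.third is None:
            raise ValueError("third moments were not supplied")
        return self.third[tuple(sorted((i, j, k)))]

    def var(self, i: int):
        return self.second_diag[i] - self.first[i] ** 2

    @property
    def species(self):
        return sorted(self.first)

    def total_first(self):
        return sum(self.first.values())


def _species_range(M):
    return range(1, M + 1)


def pre_rhs(network: ReactionNetwork, epsilon, rho, moments: MomentSet):
    """d<x_i>/dt from second moments (the pre-rate equation).

    Each reaction (substrate a, catalyst b, product c) moves probability
    flux R <x_a x_b> from a to c; the non-catalytic channel relaxes each
    mean toward rho/M.  The catalytic part sums to zero identically.
    """
    M = network.M
    rhs = {i: 0 * rho for i in _species_range(M)}
    for (a, b, c), R in network.reactions.items():
        flux = R * moments.second(a, b)
        rhs[c] += flux
        rhs[a] -= flux
    if epsilon:
        uniform = rho / M if isinstance(rho, float) else Fraction(rho, M)
        for i in _species_range(M):
            rhs[i] += epsilon * (uniform - moments.first[i])
    return rhs


def sme_concentrations(network: ReactionNetwork, epsilon, rho, second_moments):
    """Time-averaged concentrations from time-averaged second moments.

    ``second_moments`` is a MomentSet or a dict keyed by sorted pairs.
    Requires eps > 0: the expression is the steady state of the PRE and
    divides by eps, a singular limit (the eps -> 0 solution generally
    differs from the eps = 0 product-form values).
    """
    if not epsilon > 0:
        raise ValueError("the SME breaks down at eps = 0 (division by eps)")
    M = network.M
    if isinstance(second_moments, MomentSet):
        sec = second_moments.second
    else:
        sec = lambda a, b: second_moments[(min(a, b), max(a, b))]
    exact = isinstance(rho, Rational) and isinstance(epsilon, Rational)
    uniform = Fraction(rho, M) if exact else rho / M
    xbar = {i: uniform for i in _species_range(M)}
    for (a, b, c), R in network.reactions.items():
        flux = R * sec(a, b) / epsilon
        xbar[c] += flux
        xbar[a] -= flux
    return xbar


def tesm_rhs(network: ReactionNetwork, epsilon, rho, N, moments: MomentSet):
    """Time evolution of the second moments (raw third moments required).

    Returns ``(d_cross, d_diag)``: d<x_l x_m>/dt for each pair l < m and
    d<x_l (x_l - rho/N)>/dt for each species (the factorial form of the
    diagonal, which avoids mixed diagonal corrections).
    """
    if moments.third is None:
        raise ValueError("third moments are required (the system is not "
                         "closed at the second order)")
    M = network.M
    t3 = moments.third_moment
    sec = moments.second
    exact = isinstance(rho, Rational) and isinstance(epsilon, Rational)
    rn = Fraction(rho, N) if exact else rho / N
    eps_m = Fraction(epsilon, M) if exact else epsilon / M
    d_cross = {
        (l, m): 0 * rho
        for l in _species_range(M)
        for m in _species_range(M)
        if l < m
    }
    d_diag = {l: 0 * rho for l in _species_range(M)}
    for (a, b, c), R in network.reactions.items():
        # pair equations
        for (l, m) in d_cross:
            val = 0
            if (a, c) in ((l, m), (m, l)):  # moves one pair species into
                val -= rn * R * sec(b, a)   # the other
            if c == l:
                val += R * t3(a, b, m)
            if c == m:
                val += R * t3(a, b, l)
            if a in (l, m):
                val -= R * t3(b, l, m)
            d_cross[(l, m)] += val
        # diagonal (factorial) equations
        d_diag[c] += 2 * R * t3(a, b, c)
        d_diag[a] -= 2 * R * (t3(b, a, a) - rn * sec(b, a))
    if epsilon:
        for (l, m) in d_cross:
            d_cross[(l, m)] += eps_m * (
                (N - 1) * rn * (moments.first[l] + moments.first[m])
                - 2 * M * sec(l, m)
            )
        for l in d_diag:
            d_diag[l] += 2 * eps_m * (
                (N + M - 1) * rn * moments.first[l] - M * moments.second_diag[l]
            )
    return d_cross, d_diag


def two_mol_variance_relation(M: int, rho, xbar_i):
    """N = 2 stationary variance from the concentration alone.

    Var[x_i] = ((M+1) rho / (2M) - xbar) xbar.  Also returns the
    maximising concentration (M+1) rho / (4M), the maximal variance, and
    the admissibility bound xbar <= (M+1) rho / (2M).
    """
    exact = isinstance(rho, Rational) and isinstance(xbar_i, Rational)
    bound = Fraction(M + 1, 2 * M) * rho if exact else (M + 1) / (2 * M) * rho
    if xbar_i < 0 or xbar_i > bound:
        raise ValueError(
            f"concentration {xbar_i} outside the admissible range "
            f"[0, {bound}] for an N = 2 stationary state"
        )
    var = (bound - xbar_i) * xbar_i
    argmax = bound / 2
    return {
        "var": var,
        "argmax": argmax,
        "max_var": argmax * argmax,
        "bound": bound,
    }


def _pairs(M):
    return [(l, m) for l in range(1, M + 1) for m in range(l + 1, M + 1)]


def build_2mdesm(network: ReactionNetwork, epsilon, rho):
    """Linear system for the N = 2 stationary pair moments.

    Returns ``(A, b, pairs)`` with pairs ordered lexicographically; the
    solution of A xbar_pairs = b gives the stationary <x_l x_m> of the
    2-molecule mixed system.  Exact Fractions when all inputs are
    rational.
    """
    if not epsilon > 0:
        raise ValueError("the 2-molecule determination system requires "
                         "eps > 0")
    M = network.M
    pairs = _pairs(M)
    pos = {p: i for i, p in enumerate(pairs)}
    exact = all_rational(
        [epsilon, rho] + [R for R in network.reactions.values()]
    )
    zero = Fraction(0) if exact else 0.0
    A = [[zero for _ in pairs] for _ in pairs]
    diag_eps = (
        4 * Fraction(epsilon) / Fraction(rho) if exact else 4 * epsilon / rho
    )
    for i, _ in enumerate(pairs):
        A[i][i] += diag_eps
    invM = Fraction(1, M) if exact else 1.0 / M
    for (a, b, c), R in network.reactions.items():
        R = Fraction(R) if exact else float(R)
        pab = pos[(min(a, b), max(a, b))]
        pbc = pos[(min(b, c), max(b, c))]
        # loss out of the substrate-catalyst pair
        A[pab][pab] += R
        # gain into the catalyst-product pair
        A[pbc][pab] -= R
        # 1/M back-substitution terms from the SME
        for (l, m) in pairs:
            if c in (l, m):
                A[pos[(l, m)]][pab] -= invM * R
            if a in (l, m):
                A[pos[(l, m)]][pab] += invM * R
    rhs_val = (
        2 * Fraction(rho) * Fraction(epsilon) / (M * M)
        if exact
        else 2 * rho * epsilon / (M * M)
    )
    b = [rhs_val for _ in pairs]
    return A, b, pairs


def solve_2mdesm(network: ReactionNetwork, epsilon, rho):
    """Solve the 2-molecule determination system for the pair moments."""
    A, b, pairs = build_2mdesm(network, epsilon, rho)
    x = solve_linear(A, b)
    return dict(zip(pairs, x))


def two_molecule_steady(network: ReactionNetwork, epsilon, rho):
    """Full N = 2 pipeline: pair moments, then concentrations via SME."""
    sec = solve_2mdesm(network, epsilon, rho)
    xbar = sme_concentrations(network, epsilon, rho, sec)
    return sec, xbar
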