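"""Two-body catalytic reaction networks with conserved molecule number.

A network over M chemical species is a sparse collection of catalytic
reactions  i --(j)--> k : a substrate i is converted into a product k in
the presence of a catalyst j, with rate constant R_ijk > 0 (per unit
concentration and time).  Structural constraints (substrate, catalyst
and product pairwise distinct in the ways listed below; a single product
per (substrate, catalyst) pair) define the class of networks the
analytical machinery applies to.  Alongside the catalytic reactions, a
weak non-catalytic conversion i -> j at rate eps/M per molecule keeps
the dynamics irreducible when eps > 0.

The total molecule count N is conserved, so the state space is the set
of weak compositions of N into M parts (a discrete simplex).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping

from ._linalg import format_rate, parse_rate

__all__ = [
    "NetworkValidationError",
    "ReactionNetwork",
    "SystemParams",
    "StateSpace",
    "validate_network",
    "enumerate_states",
    "classify_state",
]


class NetworkValidationError(ValueError):
    """Raised when a reaction list violates the structural constraints.

    ``violations`` is a list of ``(constraint, triple)`` pairs naming
    every broken rule, so callers can report all problems at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(f"{c} at {t}" for c, t in self.violations)
        super().__init__(f"invalid reaction network: {msg}")


@dataclass(frozen=True)
class ReactionNetwork:
    """Validated catalytic reaction network.

    ``reactions`` maps 1-based (substrate, catalyst, product) triples to
    strictly positive rates (Fraction when the input was exact, float
    otherwise).  Absent triples have rate exactly zero.
    """

    M: int
    reactions: Mapping[tuple[int, int, int], object]

    def rate(self, i: int, j: int, k: int):
        """R_ijk; exact zero for absent triples."""
        return self.reactions.get((i, j, k), 0)

    @property
    def is_rational(self) -> bool:
        return all(isinstance(r, Rational) for r in self.reactions.values())

    def triples(self):
        return sorted(self.reactions.items())

    # -- serialisation -------------------------------------------------

    def to_dict(self, epsilon=0, rho=1):
        return {
            "M": self.M,
            "reactions": [
                {
                    "substrate": i,
                    "catalyst": j,
                    "product": k,
                    "rate": format_rate(r),
                }
                for (i, j, k), r in self.triples()
            ],
            "epsilon": epsilon,
            "rho": rho,
        }

    def to_json(self, path, epsilon=0, rho=1):
        with open(path, "w") as fh:
            json.dump(self.to_dict(epsilon=epsilon, rho=rho), fh, indent=1)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("i\tj\tk\trate\n")
            for (i, j, k), r in self.triples():
                fh.write(f"{i}\t{j}\t{k}\t{format_rate(r)}\n")

    @classmethod
    def from_dict(cls, data) -> "ReactionNetwork":
        raw = {
            (r["substrate"], r["catalyst"], r["product"]): r["rate"]
            for r in data["reactions"]
        }
        return validate_network(raw, data["M"])

    @classmethod
    def from_json(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_tsv(cls, path, M=None) -> "ReactionNetwork":
        raw = {}
        with open(path) as fh:
            header = fh.readline()
            if header.split()[:3] != ["i", "j", "k"]:
                raise ValueError("expected TSV header 'i\\tj\\tk\\trate'")
            for line in fh:
                if not line.strip():
                    continue
                i, j, k, rate = line.split("\t")
                raw[(int(i), int(j), int(k))] = rate.strip()
        if M is None:
            M = max(x for t in raw for x in t) if raw else 2
        return validate_network(raw, M)


def validate_network(
    raw_reactions, M: int, allow_multiple_products: bool = False
) -> ReactionNetwork:
    """Check the structural constraints and build a ReactionNetwork.

    ``raw_reactions`` maps 1-based (substrate, catalyst, product)
    triples to rates (numbers or ``"p/q"`` strings).  All violations are
    collected and reported together via NetworkValidationError.

    ``allow_multiple_products`` relaxes the one-product-per-(substrate,
    catalyst) rule.  The master equation and the simulator are well
    defined without it; the product-form steady-state theory assumes it,
    and one shipped switching fixture needs the relaxation.
    """
    if M < 2:
        raise NetworkValidationError([("species count M must be >= 2", M)])
    violations = []
    parsed = {}
    for triple, rate in dict(raw_reactions).items():
        i, j, k = triple
        if not all(1 <= x <= M for x in (i, j, k)):
            violations.append(("species index out of range", triple))
            continue
        try:
            r = parse_rate(rate)
        except (TypeError, ValueError):
            violations.append(("unparseable rate", triple))
            continue
        if not r > 0:
            violations.append(("rate must be strictly positive", triple))
            continue
        if i == j:
            violations.append(("substrate equals catalyst", triple))
        if i == k:
            violations.append(("substrate equals product", triple))
        if j == k:
            violations.append(("product equals catalyst", triple))
        parsed[triple] = r
    if not allow_multiple_products:
        seen_pairs = {}
        for (i, j, k) in sorted(parsed):
            if (i, j) in seen_pairs:
                violations.append(
                    ("two products for one substrate-catalyst pair",
                     (i, j, k))
                )
            else:
                seen_pairs[(i, j)] = k
    if violations:
        raise NetworkValidationError(violations)
    return ReactionNetwork(M=M, reactions=dict(sorted(parsed.items())))


@dataclass(frozen=True)
class SystemParams:
    """Global parameters: total molecules N, density rho = N/V, rate eps."""

    N: int
    rho: object = 1
    epsilon: object = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    @property
    def V(self):
        return self.N / self.rho if isinstance(self.rho, float) else Fraction(
            self.N
        ) / Fraction(self.rho)


class StateSpace:
    """Canonical enumeration of the discrete simplex {n >= 0 : sum n = N}.

    States are tuples ordered lexicographically descending (n_1 first),
    so distribution vectors are reproducible bit-for-bit.
    """

    def __init__(self, M: int, N: int):
        if M < 2:
            raise ValueError("M must be >= 2")
        if N < 0:
            raise ValueError("N must be >= 0")
        self.M = M
        self.N = N
        self.states: list[tuple[int, ...]] = list(_compositions(N, M))
        self.index: dict[tuple[int, ...], int] = {
            s: i for i, s in enumerate(self.states)
        }

    def __len__(self):
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def __getitem__(self, i):
        return self.states[i]

    @property
    def size_closed_form(self) -> int:
        return math.comb(self.N + self.M - 1, self.M - 1)

    def wta_indices(self) -> list[int]:
        """Indices of the single-species winner-takes-all states."""
        return [i for i, s in enumerate(self.states) if max(s) == self.N]

    def non_wta_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if max(s) < self.N]


def _compositions(N: int, M: int):
    # lexicographically descending weak compositions of N into M parts
    if M == 1:
        yield (N,)
        return
    for first in range(N, -1, -1):
        for rest in _compositions(N - first, M - 1):
            yield (first,) + rest


def enumerate_states(M: int, N: int) -> StateSpace:
    """Enumerate the state space W_{M,N} in canonical order."""
    return StateSpace(M, N)


def classify_state(n: Iterable[int]):
    """Winner-set label of a state: (l, support).

    ``l`` is the number of species holding at least one molecule and
    ``support`` the sorted tuple of their 1-based indices; l == 1 marks
    a winner-takes-all state.
    """
    n = tuple(n)
    support = tuple(i + 1 for i, c in enumerate(n) if c > 0)
    return len(support), support


def winner_sets(space: StateSpace):
    """Partition of the state space by winner-set class.

    Returns a dict mapping (l, support) to the list of state indices in
    that class; the classes partition the whole space.
    """
    out: dict[tuple[int, tuple[int, ...]], list[int]] = {}
    for idx, s in enumerate(space.states):
        out.setdefault(classify_state(s), []).append(idx)
    return out
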