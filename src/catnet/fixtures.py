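"""Built-in example networks with their known analytical facts.

Seven networks ship with the package: three three-species examples
(``triangle_a/b/c``) covering the nontrivial product form, the
connecting state to the winner-takes-all state, and the variance-rank
exchange; a four-species network whose transition graph traps
trajectories on a two-species edge despite satisfying the three-species
in/out criterion; and three hand-built non-autocatalytic conversions of
the two-species autocatalytic switching ("2TK") model, in which each of
the original species is split so that no reaction product equals its
catalyst, and the original variables are recovered as weighted species
aggregates.

Known facts are stored as data here and re-derived by the analytical
modules in the test suite — a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._linalg import parse_rate
from .network import ReactionNetwork, validate_network

__all__ = ["FixtureEntry", "get_fixture", "fixture_names", "convert_2tk",
           "random_network", "ALIASES"]


@dataclass(frozen=True)
class FixtureEntry:
    name: str
    network: ReactionNetwork
    provenance: str
    known: dict = field(default_factory=dict)


def _net(M, triples):
    return validate_network(
        {t: parse_rate(r) for t, r in triples.items()}, M
    )


_FIXTURES = {
    "triangle_a": FixtureEntry(
        name="triangle_a",
        network=_net(3, {
            (1, 2, 3): 1, (1, 3, 2): 1, (2, 1, 3): 1, (2, 3, 1): 1,
            (3, 1, 2): 1,
        }),
        provenance="three-species example with five unit-rate reactions "
                   "(the 3->(2)->1 link removed); entirely ergodic",
        known={
            "lambda": (Fraction(2, 11), Fraction(3, 11), Fraction(6, 11)),
            "entirely_ergodic": True,
        },
    ),
    "triangle_b": FixtureEntry(
        name="triangle_b",
        network=_net(3, {
            (2, 1, 3): 1, (2, 3, 1): 1, (3, 2, 1): 1, (3, 1, 2): 2,
        }),
        provenance="three-species example whose species 1 is never a "
                   "substrate: the stationary state connects to the "
                   "winner-takes-all state of species 1",
        known={
            "kappa": {2: Fraction(2, 3), 3: Fraction(1, 3)},
            "dominant": 1,
            "Lambda": (0, 2, 4),
            "entirely_ergodic": False,
        },
    ),
    "triangle_c": FixtureEntry(
        name="triangle_c",
        network=_net(3, {
            (1, 2, 3): "1997/3", (1, 3, 2): "1000/3",
            (2, 3, 1): 1, (3, 2, 1): 1,
        }),
        provenance="three-species example with strongly asymmetric "
                   "rational rates; exhibits the variance-rank exchange",
        known={
            "lambda": (
                Fraction(1, 1000), Fraction(1, 3), Fraction(1997, 3000)
            ),
            "variance_rank_changes": [3, 7],  # over the scan N = 2..20
            "entirely_ergodic": True,
        },
    ),
    "four_species_nonergodic": FixtureEntry(
        name="four_species_nonergodic",
        network=_net(4, {
            (1, 3, 2): 1, (1, 4, 3): 1, (2, 3, 1): 1, (2, 4, 3): 1,
            (3, 1, 4): 1, (4, 1, 3): 1,
        }),
        provenance="four-species network that satisfies the per-species "
                   "in/out criterion yet traps every interior trajectory "
                   "on the species-3/4 edge (rates instantiated as 1; "
                   "the verdict depends only on the sparsity pattern)",
        known={
            "entirely_ergodic": False,
            "absorbing_condition": "n1 == 0 and n2 == 0",
        },
    ),
    "five_component_2tk": FixtureEntry(
        name="five_component_2tk",
        network=_net(5, {
            (1, 4, 2): 1, (1, 5, 3): 1, (2, 3, 1): 1, (2, 5, 4): 1,
            (3, 5, 1): 1, (4, 5, 2): 1,
        }),
        provenance="five-species non-autocatalytic conversion of the "
                   "two-species autocatalytic switching model; species 5 "
                   "is shared half-and-half between the two groups",
        known={
            "nullspace_dim": 6,
            "family_supports": [
                (2, 4, 5), (1, 3, 5), (1, 2), (1, 3), (2, 4), (3, 4),
            ],
        },
    ),
    "four_component_2tk_a": FixtureEntry(
        name="four_component_2tk_a",
        network=_net(4, {
            (1, 2, 3): 1, (1, 4, 2): 1, (2, 1, 4): 1, (2, 3, 1): 1,
            (3, 2, 1): 1, (4, 1, 2): 1,
        }),
        provenance="four-species conversion of the autocatalytic "
                   "switching model (groups {1,3} and {2,4})",
        known={"family_supports": [(3, 4), (2, 4), (1, 3)]},
    ),
    "four_component_2tk_b": FixtureEntry(
        name="four_component_2tk_b",
        network=validate_network(
            {
                (1, 4, 2): 1, (1, 4, 3): 1, (2, 3, 1): 1, (2, 3, 4): 1,
                (3, 4, 1): 1, (4, 3, 2): 1,
            },
            4,
            allow_multiple_products=True,
        ),
        provenance="four-species conversion variant with the catalysis "
                   "roles of species 1,2 exchanged with 3,4; pairs (1,4) "
                   "and (2,3) each drive two products, so this network "
                   "relaxes the one-product structural rule (master "
                   "equation and simulator remain well defined)",
        known={},
    ),
}


ALIASES = {
    "fig1a": "triangle_a",
    "fig1b": "triangle_b",
    "fig1c": "triangle_c",
    "fig5a_nonergodic": "four_species_nonergodic",
}


def fixture_names():
    return sorted(_FIXTURES)


def get_fixture(name: str) -> FixtureEntry:
    key = ALIASES.get(name, name)
    if key not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {fixture_names()}"
        )
    return _FIXTURES[key]


_GROUPS_5 = {
    "A": {1: 1, 3: 1, 5: Fraction(1, 2)},
    "B": {2: 1, 4: 1, 5: Fraction(1, 2)},
}
_GROUPS_4 = {"A": {1: 1, 3: 1}, "B": {2: 1, 4: 1}}


def convert_2tk(variant: str):
    """Non-autocatalytic stand-ins for the 2TK switching model.

    Returns (fixture, aggregation groups): the aggregate n_A (and its
    complement n_B = N - n_A) reproduces the two-species switching
    variable.  Three hand-built variants ship; no general conversion
    algorithm is attempted.
    """
    if variant == "five_component":
        return get_fixture("five_component_2tk"), _GROUPS_5
    if variant == "four_component_a":
        return get_fixture("four_component_2tk_a"), _GROUPS_4
    if variant == "four_component_b":
        return get_fixture("four_component_2tk_b"), _GROUPS_4
    raise KeyError(f"unknown 2TK variant {variant!r}")


def random_network(M: int, density: float, seed: int) -> ReactionNetwork:
    """Random sparsity pattern respecting all structural constraints.

    Each ordered (substrate, catalyst) pair is active with probability
    ``density``; an active pair gets exactly one product, uniform over
    the species distinct from both, with a rate drawn as a uniform
    fraction a/b, a, b in 1..9.  Reproducible by seed.
    """
    if M < 3:
        raise ValueError("need at least three species for a catalytic "
                         "reaction")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    raw = {}
    for i in range(1, M + 1):
        for j in range(1, M + 1):
            if i == j:
                continue
            if rng.random() >= density:
                continue
            candidates = [k for k in range(1, M + 1) if k not in (i, j)]
            k = candidates[rng.integers(len(candidates))]
            rate = Fraction(
                int(rng.integers(1, 10)), int(rng.integers(1, 10))
            )
            raw[(i, j, k)] = rate
    return validate_network(raw, M)
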