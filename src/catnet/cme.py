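"""Exact chemical master equation machinery on the enumerated state space.

The CME generator is assembled as a sparse matrix over the canonical
state enumeration; its null space (per closed communicating class) gives
exact stationary distributions, which serve as the brute-force oracle
for every analytical formula in :mod:`catnet.steady` and
:mod:`catnet.moments`.  Entire ergodicity of the catalytic-only dynamics
is decided by strong-connectivity analysis of the transition graph
restricted to the non-winner-takes-all states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .moments import MomentSet
from .network import ReactionNetwork, StateSpace, SystemParams, enumerate_states

__all__ = [
    "Distribution",
    "ErgodicityReport",
    "StateSpaceTooLarge",
    "build_generator",
    "stationary_exact",
    "moments_from_distribution",
    "marginal_from_distribution",
    "ergodicity_check",
]

#: hard cap on enumerated states for exact solves
DEFAULT_STATE_CAP = 200_000

#: dense null-space solves below this size, sparse eigensolver above
DENSE_SWITCH = 2000


class StateSpaceTooLarge(ValueError):
    pass


@dataclass
class Distribution:
    """Probability vector aligned with a StateSpace enumeration."""

    space: StateSpace
    p: np.ndarray
    source: str = "exact"  # exact | analytic | empirical
    context: dict = field(default_factory=dict)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.space),):
            raise ValueError("probability vector does not match state space")
        if (self.p < -1e-12).any():
            raise ValueError("negative probabilities")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities do not sum to 1")

    def prob(self, state) -> float:
        return float(self.p[self.space.index[tuple(state)]])

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("\t".join(f"n_{i+1}" for i in range(self.space.M)))
            fh.write("\tprobability\n")
            for state, pi in zip(self.space.states, self.p):
                fh.write("\t".join(map(str, state)) + f"\t{float(pi)!r}\n")

    @classmethod
    def from_tsv(cls, path, source="exact", context=None):
        with open(path) as fh:
            fh.readline()
            states, probs = [], []
            for line in fh:
                *ns, pr = line.split("\t")
                states.append(tuple(map(int, ns)))
                probs.append(float(pr))
        N = sum(states[0])
        space = enumerate_states(len(states[0]), N)
        p = np.zeros(len(space))
        for s, pr in zip(states, probs):
            p[space.index[s]] = pr
        return cls(space, p, source=source, context=context or {})


def _transitions(network: ReactionNetwork, params: SystemParams, state):
    """Yield (target_state, rate) for all reactions leaving ``state``."""
    N = params.N
    rho = float(params.rho)
    eps = float(params.epsilon)
    M = network.M
    n = state
    for (i, j, k), R in network.reactions.items():
        ni, nj = n[i - 1], n[j - 1]
        if ni > 0 and nj > 0:
            rate = (rho / N) * float(R) * ni * nj
            tgt = list(n)
            tgt[i - 1] -= 1
            tgt[k - 1] += 1
            yield tuple(tgt), rate
    if eps > 0:
        for i in range(1, M + 1):
            ni = n[i - 1]
            if ni == 0:
                continue
            rate = eps / M * ni
            for j in range(1, M + 1):
                if j == i:
                    continue
                tgt = list(n)
                tgt[i - 1] -= 1
                tgt[j - 1] += 1
                yield tuple(tgt), rate


def build_generator(
    network: ReactionNetwork,
    params: SystemParams,
    space: StateSpace | None = None,
    state_cap: int = DEFAULT_STATE_CAP,
):
    """Assemble the CME generator Q (columns = source states).

    Entry (m, n) is the total rate of the transition n -> m; diagonal
    entries make every column sum to zero.  Catalytic channel:
    n -> n - e_i + e_k at rate (rho/N) R_ijk n_i n_j; non-catalytic
    channel: n -> n - e_i + e_j at rate (eps/M) n_i for each j != i.
    """
    if space is None:
        space = enumerate_states(network.M, params.N)
    if len(space) > state_cap:
        raise StateSpaceTooLarge(
            f"{len(space)} states exceeds the cap of {state_cap}"
        )
    rows, cols, vals = [], [], []
    for col, state in enumerate(space.states):
        out = 0.0
        for tgt, rate in _transitions(network, params, state):
            rows.append(space.index[tgt])
            cols.append(col)
            vals.append(rate)
            out += rate
        if out:
            rows.append(col)
            cols.append(col)
            vals.append(-out)
    Q = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(space), len(space)), dtype=float
    )
    return Q


def _closed_classes(Q: sp.csc_matrix):
    """Closed communicating classes of the jump chain (lists of indices)."""
    coo = Q.tocoo()
    g = nx.DiGraph()
    g.add_nodes_from(range(Q.shape[0]))
    g.add_edges_from(
        (int(c), int(r))
        for r, c, v in zip(coo.row, coo.col, coo.data)
        if r != c and v > 0
    )
    cond = nx.condensation(g)
    closed = [
        sorted(cond.nodes[node]["members"])
        for node in cond.nodes
        if cond.out_degree(node) == 0
    ]
    closed.sort()
    return closed


def _null_vector(Qc: np.ndarray) -> np.ndarray:
    """One stationary vector of a generator restricted to a closed class."""
    if Qc.shape == (1, 1):
        return np.array([1.0])
    _, s, vt = np.linalg.svd(Qc)
    tol = s[0] * 1e-10 if s[0] > 0 else 1e-14
    dim = int((s <= tol).sum())
    if dim != 1:
        raise np.linalg.LinAlgError(
            "ill-conditioned null space on a closed class: singular values "
            f"{s[-max(dim, 2):]}"
        )
    v = vt[-1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def stationary_exact(
    Q: sp.csc_matrix,
    space: StateSpace,
    restrict_to=None,
    context=None,
) -> list[Distribution]:
    """Exact stationary distributions, one per closed communicating class.

    ``restrict_to`` (an iterable of state indices) limits the solve to a
    single closed class, e.g. the non-WTA states of an entirely ergodic
    catalytic-only system.  The null-space dimension of each restricted
    generator must be exactly one, otherwise a diagnostic error with the
    singular spectrum is raised.
    """
    context = dict(context or {})
    if restrict_to is not None:
        idx = np.asarray(sorted(restrict_to), dtype=int)
        classes = [list(idx)]
    else:
        classes = _closed_classes(Q)
    dists = []
    for cls_idx in classes:
        idx = np.asarray(cls_idx, dtype=int)
        Qc = Q[np.ix_(idx, idx)]
        if len(idx) <= DENSE_SWITCH:
            v = _null_vector(np.asarray(Qc.todense()))
        else:
            # shift-invert around zero on the sparse restricted generator
            w, vecs = sp.linalg.eigs(Qc.tocsc(), k=1, sigma=0.0)
            v = np.real(vecs[:, 0])
            if v.sum() < 0:
                v = -v
            v = np.clip(v, 0.0, None)
            v = v / v.sum()
        p = np.zeros(len(space))
        p[idx] = v
        dists.append(
            Distribution(space, p, source="exact", context=context)
        )
    return dists


def moments_from_distribution(
    dist: Distribution, params: SystemParams
) -> MomentSet:
    """First and second concentration moments by direct summation."""
    space = dist.space
    M, N = space.M, space.N
    rho = float(params.rho)
    ns = np.asarray(space.states, dtype=float) * (rho / N)  # x = n rho / N
    p = dist.p
    first = {i + 1: float(p @ ns[:, i]) for i in range(M)}
    cross = {
        (i + 1, j + 1): float(p @ (ns[:, i] * ns[:, j]))
        for i in range(M)
        for j in range(i + 1, M)
    }
    diag = {i + 1: float(p @ (ns[:, i] ** 2)) for i in range(M)}
    return MomentSet(
        first=first,
        second_cross=cross,
        second_diag=diag,
        context={"N": N, "rho": rho, "epsilon": params.epsilon, "M": M},
    )


def marginal_from_distribution(dist: Distribution, species: int) -> np.ndarray:
    """Marginal distribution of one species over counts 0..N."""
    space = dist.space
    out = np.zeros(space.N + 1)
    col = species - 1
    for state, pi in zip(space.states, dist.p):
        out[state[col]] += pi
    return out


@dataclass
class ErgodicityReport:
    """Verdict and supporting structure for catalytic-only ergodicity."""

    entirely_ergodic: bool
    M: int
    N: int
    n_states: int
    non_wta_scc_count: int
    escapes_to_wta: bool
    closed_classes: list  # closed classes within W \ I (as state tuples)
    criterion_m3: bool | None = None  # in/out-degree criterion, M = 3 only
    criterion_agrees: bool | None = None

    @property
    def verdict(self) -> str:
        return "entirely_ergodic" if self.entirely_ergodic else "not"


def criterion_m3(network: ReactionNetwork) -> bool:
    """Three-species ergodicity criterion on the rate tensor alone.

    For every species k there must be at least one reaction producing k
    (moving off the boundary n_k = 0) and at least one consuming k
    (approaching it).  Necessary and sufficient for M = 3 only.
    """
    if network.M != 3:
        raise ValueError("criterion defined for M = 3")
    for k in range(1, 4):
        produces = any(t[2] == k for t in network.reactions)
        consumes = any(t[0] == k for t in network.reactions)
        if not (produces and consumes):
            return False
    return True


def ergodicity_check(
    network: ReactionNetwork, N: int, state_cap: int = DEFAULT_STATE_CAP
) -> ErgodicityReport:
    """Decide entire ergodicity of the catalytic-only dynamics exactly.

    Builds the directed catalytic transition graph on W_{M,N} and checks
    that the non-WTA states form a single strongly connected class with
    no escape (the WTA states are individually frozen and structurally
    unreachable, since a reaction needs two distinct species present).
    """
    space = enumerate_states(network.M, N)
    if len(space) > state_cap:
        raise StateSpaceTooLarge(
            f"{len(space)} states exceeds the cap of {state_cap}"
        )
    params = SystemParams(N=N, rho=1, epsilon=0)
    g = nx.DiGraph()
    g.add_nodes_from(range(len(space)))
    for col, state in enumerate(space.states):
        for tgt, rate in _transitions(network, params, state):
            if rate > 0:
                g.add_edge(col, space.index[tgt])
    non_wta = set(space.non_wta_indices())
    wta = set(space.wta_indices())
    escapes = any(v in wta for u in non_wta for v in g.successors(u))
    sub = g.subgraph(non_wta)
    sccs = list(nx.strongly_connected_components(sub))
    cond = nx.condensation(sub, scc=sccs)
    closed = [
        sorted(space.states[i] for i in cond.nodes[node]["members"])
        for node in cond.nodes
        if cond.out_degree(node) == 0
    ]
    closed.sort()
    ergodic = len(sccs) == 1 and not escapes
    crit = agrees = None
    if network.M == 3:
        crit = criterion_m3(network)
        agrees = crit == ergodic
    return ErgodicityReport(
        entirely_ergodic=ergodic,
        M=network.M,
        N=N,
        n_states=len(space),
        non_wta_scc_count=len(sccs),
        escapes_to_wta=escapes,
        closed_classes=closed,
        criterion_m3=crit,
        criterion_agrees=agrees,
    )
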