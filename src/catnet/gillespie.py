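"""Exact stochastic simulation (direct method) of the mixed dynamics.

Samples trajectories of the jump process whose master equation the rest
of the package analyses: catalytic events i -> k in the presence of a
catalyst j at propensity (rho/N) R_ijk n_i n_j, and non-catalytic
conversions i -> j at propensity (eps/M) n_i per target species (the
self-conversion j = i is a no-op and is excluded from the event list).
Time averages are occupancy-time weighted, matching the long-run time
integral of the process, not per-event averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ReactionNetwork, SystemParams

__all__ = [
    "Trajectory",
    "TimeAverages",
    "propensities",
    "simulate",
    "random_initial_state",
    "time_average",
    "aggregate_observable",
]


@dataclass
class Trajectory:
    """Event-resolved sample path: state just after each event time.

    ``states[0]`` is the initial condition at time 0; ``times[e]`` is
    the time of event e (times[0] = 0).  ``frozen`` marks runs that hit
    a state with zero total propensity before the requested number of
    reactions.
    """

    times: np.ndarray
    states: np.ndarray
    seed: int
    params: SystemParams
    network: ReactionNetwork
    frozen: bool = False

    @property
    def n_reactions(self) -> int:
        return len(self.times) - 1

    def to_tsv(self, path, thin: int = 1):
        M = self.states.shape[1]
        with open(path, "w") as fh:
            fh.write("time\t" + "\t".join(f"n_{i+1}" for i in range(M)) + "\n")
            for e in range(0, len(self.times), thin):
                fh.write(
                    f"{float(self.times[e])!r}\t"
                    + "\t".join(str(int(v)) for v in self.states[e])
                    + "\n"
                )


def propensities(network: ReactionNetwork, params: SystemParams, n):
    """Event list with rates at state n.

    Returns a list of ``(rate, delta)`` with delta the M-vector change;
    only events with positive rate are listed (a frozen state yields an
    empty list).
    """
    N, M = params.N, network.M
    rho = float(params.rho)
    eps = float(params.epsilon)
    events = []
    for (i, j, k), R in network.reactions.items():
        ni, nj = n[i - 1], n[j - 1]
        if ni > 0 and nj > 0:
            delta = [0] * M
            delta[i - 1] -= 1
            delta[k - 1] += 1
            events.append(((rho / N) * float(R) * ni * nj, tuple(delta)))
    if eps > 0:
        for i in range(M):
            if n[i] == 0:
                continue
            rate = eps / M * n[i]
            for j in range(M):
                if j == i:
                    continue
                delta = [0] * M
                delta[i] -= 1
                delta[j] += 1
                events.append((rate, tuple(delta)))
    return events


def random_initial_state(network, params, rng):
    """Uniform draw from the non-WTA states (mean count N/M by symmetry
    of the uniform measure over the simplex).

    Stars-and-bars sampling with rejection of winner-takes-all draws,
    so no state enumeration is needed even for large N.
    """
    M, N = network.M, params.N
    while True:
        bars = np.sort(rng.choice(N + M - 1, size=M - 1, replace=False))
        edges = np.concatenate(([-1], bars, [N + M - 1]))
        counts = np.diff(edges) - 1
        if counts.max() < N:
            return tuple(int(c) for c in counts)


def simulate(
    network: ReactionNetwork,
    params: SystemParams,
    n0,
    seed: int,
    n_reactions: int,
) -> Trajectory:
    """Direct-method simulation for a fixed number of reaction events.

    Exponential waiting times from the total propensity, categorical
    event choice proportional to the individual propensities; two
    uniforms per event from a PCG64 generator, so a fixed seed gives a
    bit-for-bit reproducible trajectory.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    n0 = tuple(int(v) for v in n0)
    if sum(n0) != params.N:
        raise ValueError("initial state does not hold N molecules")
    rng = np.random.default_rng(seed)
    M = network.M
    N = params.N
    rho_over_N = float(params.rho) / N
    eps_over_M = float(params.epsilon) / M

    cat = [
        (i - 1, j - 1, k - 1, float(R))
        for (i, j, k), R in network.reactions.items()
    ]
    n_cat = len(cat)
    noncat = (
        [(i, j) for i in range(M) for j in range(M) if j != i]
        if eps_over_M > 0
        else []
    )
    n_events = n_cat + len(noncat)

    times = np.empty(n_reactions + 1)
    states = np.empty((n_reactions + 1, M), dtype=np.int64)
    times[0] = 0.0
    states[0] = n0

    n = list(n0)
    t = 0.0
    rates = [0.0] * n_events
    frozen = False
    e_done = 0
    for step in range(n_reactions):
        total = 0.0
        for idx in range(n_cat):
            i, j, k, R = cat[idx]
            r = rho_over_N * R * n[i] * n[j]
            rates[idx] = r
            total += r
        for idx, (i, j) in enumerate(noncat, start=n_cat):
            r = eps_over_M * n[i]
            rates[idx] = r
            total += r
        if total <= 0.0:
            frozen = True
            break
        t += rng.exponential(1.0 / total)
        u = rng.random() * total
        acc = 0.0
        chosen = n_events - 1
        for idx in range(n_events):
            acc += rates[idx]
            if u < acc:
                chosen = idx
                break
        if chosen < n_cat:
            i, j, k, _ = cat[chosen]
            n[i] -= 1
            n[k] += 1
        else:
            i, j = noncat[chosen - n_cat]
            n[i] -= 1
            n[j] += 1
        e_done += 1
        times[e_done] = t
        states[e_done] = n
    return Trajectory(
        times=times[: e_done + 1],
        states=states[: e_done + 1],
        seed=seed,
        params=params,
        network=network,
        frozen=frozen,
    )


@dataclass
class TimeAverages:
    """Occupancy-time weighted statistics of a trajectory tail."""

    xbar: np.ndarray
    second_cross: dict
    second_diag: np.ndarray
    marginals: np.ndarray  # shape (M, N+1), occupancy probabilities
    burn_in_reactions: int
    total_time: float

    def var(self, i: int) -> float:
        return float(self.second_diag[i - 1] - self.xbar[i - 1] ** 2)


def _holding_times(traj: Trajectory, burn_in: int):
    times = traj.times[burn_in:]
    states = traj.states[burn_in:-1] if len(traj.times) > burn_in + 1 else None
    if states is None or len(times) < 2:
        raise ValueError("burn-in leaves no occupancy time to average over")
    dt = np.diff(times)
    return states, dt


def time_average(traj: Trajectory, burn_in_reactions: int = 0) -> TimeAverages:
    """Time-weighted averages and empirical marginals after burn-in.

    A frozen trajectory contributes its final state as a point mass.
    """
    if traj.frozen:
        # the process spends unbounded time in the frozen state, so the
        # long-run time average is a point mass there
        M = traj.states.shape[1]
        n = traj.states[-1]
        x = n * float(traj.params.rho) / traj.params.N
        marg = np.zeros((M, traj.params.N + 1))
        for i in range(M):
            marg[i, n[i]] = 1.0
        return TimeAverages(
            xbar=x.astype(float),
            second_cross={
                (i + 1, j + 1): float(x[i] * x[j])
                for i in range(M)
                for j in range(i + 1, M)
            },
            second_diag=(x * x).astype(float),
            marginals=marg,
            burn_in_reactions=burn_in_reactions,
            total_time=float("inf"),
        )
    states, dt = _holding_times(traj, burn_in_reactions)
    M = states.shape[1]
    N = traj.params.N
    scale = float(traj.params.rho) / N
    T = dt.sum()
    x = states * scale
    xbar = (dt @ x) / T
    cross = {
        (i + 1, j + 1): float((dt * x[:, i] * x[:, j]).sum() / T)
        for i in range(M)
        for j in range(i + 1, M)
    }
    diag = (dt @ (x * x)) / T
    marg = np.zeros((M, N + 1))
    for i in range(M):
        marg[i] = np.bincount(states[:, i], weights=dt, minlength=N + 1) / T
    return TimeAverages(
        xbar=xbar,
        second_cross=cross,
        second_diag=diag,
        marginals=marg,
        burn_in_reactions=burn_in_reactions,
        total_time=float(T),
    )


def aggregate_observable(
    traj: Trajectory, groups: dict, burn_in_reactions: int = 0
):
    """Weighted species aggregates along the trajectory.

    ``groups`` maps a name to a dict species -> weight (weights may be
    fractional, e.g. a shared species split between two groups).
    Returns a dict name -> (series, histogram) where ``series`` is the
    aggregate at each event and ``histogram`` maps aggregate values to
    occupancy probabilities over the post-burn-in tail.
    """
    M = traj.states.shape[1]
    out = {}
    states, dt = _holding_times(traj, burn_in_reactions)
    T = dt.sum()
    for name, weights in groups.items():
        for sp in weights:
            if not 1 <= sp <= M:
                raise ValueError(f"group {name!r} references unknown "
                                 f"species {sp}")
        w = np.zeros(M)
        for sp, wt in weights.items():
            w[sp - 1] = float(wt)
        series = traj.states @ w
        tail = states @ w
        values, inverse = np.unique(tail, return_inverse=True)
        occ = np.bincount(inverse, weights=dt) / T
        out[name] = (series, dict(zip(values.tolist(), occ.tolist())))
    return out
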