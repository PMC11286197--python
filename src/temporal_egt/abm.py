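"""Agent-based Monte Carlo simulation of games on activity-driven networks.

One evolutionary step at time t:

1. *game phase* — build the integrated network G_delta(t) from delta fresh
   activity-driven snapshots; every individual accumulates payoff by playing
   the pairwise game against each of its neighbours (isolated individuals
   hold payoff 0);
2. *update phase* — every individual with at least one neighbour picks one
   uniformly at random and adopts its strategy with the Fermi probability
   ``1 / (1 + exp(-beta (P_v - P_u)))``.  The baseline scheme is
   synchronous: all decisions are evaluated against the pre-update state.

Observables are the activity moments per strategy,
``I^k_i = (1/N) sum_{u: s_u = i} a_u^k`` (``I^0_i`` is the frequency of
strategy i), recorded every step.  At stationarity under weak selection they
satisfy ``I^k_i = <a^k> x_i``, the slow-manifold law the deterministic
theory predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .activity_net import (
    ActivityDistribution,
    IntegratedGraph,
    TemporalNetConfig,
    _snapshot_codes,
    _codes_to_edges,
    integrate_window,
    spawn_rng,
)
from .game_theory import PayoffMatrix

__all__ = [
    "PopulationState",
    "ABMParams",
    "MomentTable",
    "ABMResult",
    "ReplicateSummary",
    "fermi_prob",
    "accumulate_payoffs",
    "update_strategies",
    "empirical_moments",
    "run_abm",
    "run_replicates",
    "expected_moment_change",
]


@dataclass
class PopulationState:
    """Activities (fixed) and strategies (evolving) of the N individuals."""

    activities: np.ndarray
    strategies: np.ndarray
    time: int = 0

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        self.strategies = np.asarray(self.strategies, dtype=np.int64)
        if self.activities.shape != self.strategies.shape or self.activities.ndim != 1:
            raise ValueError("activities and strategies must be 1-d vectors of equal length")

    @property
    def N(self) -> int:
        return self.activities.size


@dataclass(frozen=True)
class ABMParams:
    """Protocol constants of one simulation run.

    ``relax_steps`` evolutionary steps are discarded before averaging the
    moment observables over ``record_steps`` further steps (defaults 750 and
    250), with moments recorded up to order ``k_max``.
    """

    game: PayoffMatrix
    activity: ActivityDistribution
    net: TemporalNetConfig
    beta: float
    relax_steps: int = 750
    record_steps: int = 250
    k_max: int = 8
    scheme: str = "synchronous"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.relax_steps < 0 or self.record_steps < 1:
            raise ValueError("need relax_steps >= 0 and record_steps >= 1")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if self.scheme not in ("synchronous", "asynchronous-random-order"):
            raise ValueError(f"unknown update scheme {self.scheme!r}")
        if self.game.n < 2:
            raise ValueError("need at least 2 strategies")

    @property
    def steps(self) -> int:
        return self.relax_steps + self.record_steps


@dataclass(frozen=True)
class MomentTable:
    """Per-strategy activity moments I^k at one instant; row i, column k."""

    values: np.ndarray  # (n_strategies, k_max + 1)

    @property
    def frequencies(self) -> np.ndarray:
        return self.values[:, 0]

    def validate(self, atol: float = 1e-12) -> None:
        v = self.values
        if abs(v[:, 0].sum() - 1.0) > atol:
            raise AssertionError("strategy frequencies must sum to 1")
        if np.any(v < -atol):
            raise AssertionError("moments must be non-negative")
        if np.any(v[:, 1:] > v[:, :-1] + atol):
            raise AssertionError("I^{k+1} <= I^k must hold for activities in (0, 1]")


def fermi_prob(dP, beta: float):
    """Imitation probability 1/(1 + exp(-beta*dP)); overflow-safe (saturates
    to 0/1 for large |beta*dP|) and exactly 1/2 at dP = 0 or beta = 0."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return expit(beta * np.asarray(dP, dtype=float))


def accumulate_payoffs(graph: IntegratedGraph, strategies: np.ndarray, game: PayoffMatrix) -> np.ndarray:
    """Accumulated payoff P_u = sum over neighbours v of a_{s(u), s(v)}."""
    strategies = np.asarray(strategies, dtype=np.int64)
    if strategies.size != graph.n_nodes:
        raise ValueError("strategy vector length must match the graph")
    if strategies.size and (strategies.min() < 0 or strategies.max() >= game.n):
        raise ValueError("strategy index out of range for the payoff matrix")
    P = np.zeros(graph.n_nodes)
    if graph.n_edges:
        u, v = graph.edges[:, 0], graph.edges[:, 1]
        A = game.entries
        np.add.at(P, u, A[strategies[u], strategies[v]])
        np.add.at(P, v, A[strategies[v], strategies[u]])
    return P


def _neighbour_csr(graph: IntegratedGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbour lists in CSR form: (degrees, offsets, flat neighbour array)."""
    N = graph.n_nodes
    if graph.n_edges == 0:
        return np.zeros(N, np.int64), np.zeros(N + 1, np.int64), np.empty(0, np.int64)
    src = np.concatenate([graph.edges[:, 0], graph.edges[:, 1]])
    dst = np.concatenate([graph.edges[:, 1], graph.edges[:, 0]])
    order = np.argsort(src, kind="stable")
    deg = np.bincount(src, minlength=N)
    offsets = np.zeros(N + 1, np.int64)
    np.cumsum(deg, out=offsets[1:])
    return deg, offsets, dst[order]


def update_strategies(
    graph: IntegratedGraph,
    strategies: np.ndarray,
    payoffs: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    scheme: str = "synchronous",
) -> np.ndarray:
    """One imitation sweep; returns the new strategy vector.

    Synchronous: every connected node picks a uniform neighbour and decides
    from the pre-update payoffs/strategies simultaneously.  The asynchronous
    variant revises nodes one at a time in a random order, re-reading
    strategies (payoffs stay frozen within the sweep).  Isolated nodes never
    change.
    """
    strategies = np.asarray(strategies, dtype=np.int64)
    deg, offsets, flat = _neighbour_csr(graph)
    connected = deg > 0
    if scheme == "synchronous":
        new = strategies.copy()
        if not connected.any():
            return new
        idx = np.flatnonzero(connected)
        pick = offsets[idx] + rng.integers(0, deg[idx])
        models = flat[pick]
        p = fermi_prob(payoffs[models] - payoffs[idx], beta)
        adopt = rng.random(idx.size) < p
        new[idx[adopt]] = strategies[models[adopt]]
        return new
    if scheme == "asynchronous-random-order":
        new = strategies.copy()
        order = rng.permutation(graph.n_nodes)
        for u in order:
            if deg[u] == 0:
                continue
            v = flat[offsets[u] + rng.integers(0, deg[u])]
            if rng.random() < fermi_prob(payoffs[v] - payoffs[u], beta):
                new[u] = new[v]
        return new
    raise ValueError(f"unknown update scheme {scheme!r}")


def empirical_moments(state: PopulationState, k_max: int, n_strategies: int | None = None) -> MomentTable:
    """Moment table I^k_i = (1/N) sum_{u: s_u=i} a_u^k, k = 0..k_max."""
    n = int(n_strategies if n_strategies is not None else state.strategies.max() + 1)
    N = state.N
    powers = state.activities[:, None] ** np.arange(k_max + 1)[None, :]
    vals = np.zeros((n, k_max + 1))
    for i in range(n):
        mask = state.strategies == i
        if mask.any():
            vals[i] = powers[mask].sum(axis=0)
    return MomentTable(vals / N)


def _init_state(params: ABMParams, initial_frequencies, rng: np.random.Generator,
                activities: np.ndarray | None = None) -> PopulationState:
    x0 = np.asarray(initial_frequencies, dtype=float)
    if x0.shape != (params.game.n,):
        raise ValueError("initial frequencies must have one entry per strategy")
    if np.any(x0 < 0) or abs(x0.sum() - 1.0) > 1e-9:
        raise ValueError("initial frequencies must lie on the probability simplex")
    N = params.net.N
    if activities is None:
        activities = params.activity.sample(N, rng)
    strategies = rng.choice(params.game.n, size=N, p=x0)
    return PopulationState(activities, strategies)


@dataclass
class ABMResult:
    """Per-step moment trajectory of one replicate."""

    params: ABMParams
    moments: np.ndarray          # (steps + 1, n_strategies, k_max + 1); index 0 = initial state
    edge_counts: np.ndarray      # (steps,)
    seed: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.moments[:, :, 0]

    def stationary_moments(self) -> np.ndarray:
        """Time average over the recording window (after relaxation)."""
        return self.moments[self.params.relax_steps + 1 :].mean(axis=0)


def run_abm(
    params: ABMParams,
    initial_frequencies,
    seed: int,
    *,
    replicate: int = 0,
    activities: np.ndarray | None = None,
) -> ABMResult:
    """Simulate one replicate of the two-phase evolutionary process.

    Randomness is split per (seed, replicate, window) so runs are
    reproducible and replicates independent.  Supplying ``activities``
    freezes the activity draw across replicates.
    """
    rng_init = spawn_rng(seed, replicate, 0)
    state = _init_state(params, initial_frequencies, rng_init, activities)
    N, m, delta = params.net.N, params.net.m, params.net.delta
    n, k_max = params.game.n, params.k_max
    A = params.game.entries

    powers = state.activities[:, None] ** np.arange(k_max + 1)[None, :]
    moments = np.empty((params.steps + 1, n, k_max + 1))
    edge_counts = np.empty(params.steps, dtype=np.int64)

    def record(slot: int, strategies: np.ndarray) -> None:
        for i in range(n):
            mask = strategies == i
            moments[slot, i] = powers[mask].sum(axis=0) / N if mask.any() else 0.0

    record(0, state.strategies)
    for step in range(params.steps):
        rng = spawn_rng(seed, replicate, step + 1)
        codes = np.concatenate([np.unique(_snapshot_codes(state.activities, m, rng)) for _ in range(delta)])
        graph = IntegratedGraph(N, _codes_to_edges(np.unique(codes), N), window=(step, delta))
        payoffs = accumulate_payoffs(graph, state.strategies, params.game)
        state.strategies = update_strategies(graph, state.strategies, payoffs, params.beta, rng, params.scheme)
        state.time += 1
        edge_counts[step] = graph.n_edges
        record(step + 1, state.strategies)
    return ABMResult(params, moments, edge_counts, seed)


@dataclass
class ReplicateSummary:
    """Stationary moments across replicate initial conditions."""

    params: ABMParams
    stationary: np.ndarray  # (n_replicates, n_strategies, k_max + 1)
    seed: int

    @property
    def mean(self) -> np.ndarray:
        return self.stationary.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.stationary.std(axis=0, ddof=1)

    def manifold_deviation(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-replicate deviation d^k_i = I^k_i - <a^k> I^0_i and its SE.

        Returns (mean deviation, standard error) over replicates; the
        slow-manifold law predicts mean 0 for every k and strategy.
        """
        mu = self.params.activity.moments(self.params.k_max)
        d = self.stationary - mu[None, None, :] * self.stationary[:, :, 0:1]
        R = d.shape[0]
        return d.mean(axis=0), d.std(axis=0, ddof=1) / np.sqrt(R)


def run_replicates(
    params: ABMParams,
    initial_frequencies,
    n_replicates: int,
    seed: int,
    *,
    freeze_activities: bool = False,
) -> ReplicateSummary:
    """Run ``n_replicates`` independent replicates (fresh strategy assignment
    and, unless frozen, fresh activities) and collect stationary moments."""
    stationary = np.empty((n_replicates, params.game.n, params.k_max + 1))
    frozen = params.activity.sample(params.net.N, spawn_rng(seed, 0, 0)) if freeze_activities else None
    for r in range(n_replicates):
        res = run_abm(params, initial_frequencies, seed, replicate=r, activities=frozen)
        stationary[r] = res.stationary_moments()
    return ReplicateSummary(params, stationary, seed)


def expected_moment_change(
    graph: IntegratedGraph,
    state: PopulationState,
    game: PayoffMatrix,
    beta: float,
    k_max: int,
    n_strategies: int | None = None,
) -> np.ndarray:
    """Exact expected one-step change of I^k_i on a *frozen* graph and state.

    Enumerates every (focal, neighbour) imitation channel of the synchronous
    update: E[dI^k_i] = (1/N) sum_u a_u^k sum_{v ~ u} (1/deg_u)
    F(P_v - P_u) (1[s_v = i] - 1[s_u = i]).  Used as the enumeration oracle
    tying the stochastic update rule to the mean-field gain/loss structure.
    """
    n = int(n_strategies if n_strategies is not None else game.n)
    payoffs = accumulate_payoffs(graph, state.strategies, game)
    deg, offsets, flat = _neighbour_csr(graph)
    out = np.zeros((n, k_max + 1))
    ks = np.arange(k_max + 1)
    for u in range(state.N):
        if deg[u] == 0:
            continue
        a_k = state.activities[u] ** ks
        su = state.strategies[u]
        for v in flat[offsets[u] : offsets[u + 1]]:
            p = float(fermi_prob(payoffs[v] - payoffs[u], beta)) / deg[u]
            sv = state.strategies[v]
            if sv != su:
                out[sv] += p * a_k
                out[su] -= p * a_k
    return out / state.N
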