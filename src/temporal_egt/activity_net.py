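"""Activity-driven temporal networks.

An activity-driven network over ``N`` individuals evolves in discrete
snapshots.  Each individual ``u`` carries an activity potential
``a_u in (0, 1]`` drawn once from a density ``f(a)``.  Per snapshot, ``u``
activates with probability ``a_u`` and, if active, wires ``m`` undirected
links to partners chosen uniformly at random (no self-links, no duplicate
links).  All links are discarded after the snapshot.  The *integrated*
network over a window of ``delta`` consecutive snapshots is the simple-graph
union of the snapshot edge sets, and is the interaction graph for one
evolutionary step.

This module provides the distribution object (with an exact moment oracle
``<a^k>``), the snapshot and window generators, and the closed-form mean
degree of the integrated network, ``(a + <a>) * m * delta`` for a node of
activity ``a`` in the infinite-population limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate as _sciint

__all__ = [
    "ActivityDistribution",
    "TemporalNetConfig",
    "InstantaneousGraph",
    "IntegratedGraph",
    "sample_activities",
    "generate_instantaneous",
    "integrate_window",
    "mean_degree_theory",
    "spawn_rng",
    "write_edgelist",
    "read_edgelist",
]


def spawn_rng(seed: int, *path: int) -> np.random.Generator:
    """Deterministic child generator for (seed, path) without stream overlap.

    ``path`` indexes e.g. (replicate, window) so that each window of each
    replicate owns an independent, reproducible stream.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(p) for p in path)))


@dataclass(frozen=True)
class ActivityDistribution:
    """Probability density ``f(a)`` of activity potentials on a support in (0, 1].

    Three families are supported:

    ``uniform``
        constant density on ``[low, high]`` (``params = (low, high)``);
    ``point_mass``
        all mass at ``a0`` (``params = (a0,)``);
    ``tabulated``
        density given on a grid, interpolated linearly (``params`` unused;
        ``grid``/``density`` arrays supplied instead).
    """

    family: str
    params: tuple = ()
    grid: np.ndarray | None = None
    density: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family == "uniform":
            low, high = self.params
            if not (0.0 < low < high <= 1.0):
                raise ValueError(f"uniform support [{low}, {high}] must lie within (0, 1] with low < high")
        elif self.family == "point_mass":
            (a0,) = self.params
            if not (0.0 < a0 <= 1.0):
                raise ValueError(f"point mass location {a0} outside (0, 1]")
        elif self.family == "tabulated":
            grid = np.asarray(self.grid, dtype=float)
            dens = np.asarray(self.density, dtype=float)
            if grid.ndim != 1 or grid.shape != dens.shape or grid.size < 2:
                raise ValueError("tabulated family needs matching 1-d grid/density arrays (size >= 2)")
            if not (0.0 < grid[0] and grid[-1] <= 1.0 and np.all(np.diff(grid) > 0)):
                raise ValueError("tabulated grid must be increasing and lie within (0, 1]")
            if np.any(dens < 0):
                raise ValueError("tabulated density must be non-negative")
            total = np.trapezoid(dens, grid)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"tabulated density integrates to {total!r}, not 1")
            object.__setattr__(self, "grid", grid)
            object.__setattr__(self, "density", dens)
        else:
            raise ValueError(f"unknown activity distribution family {self.family!r}")

    # -- constructors -----------------------------------------------------

    @classmethod
    def uniform(cls, low: float = 0.001, high: float = 1.0) -> "ActivityDistribution":
        return cls("uniform", (float(low), float(high)))

    @classmethod
    def point_mass(cls, a0: float) -> "ActivityDistribution":
        return cls("point_mass", (float(a0),))

    @classmethod
    def tabulated(cls, grid: Sequence[float], density: Sequence[float]) -> "ActivityDistribution":
        return cls("tabulated", (), grid=np.asarray(grid, float), density=np.asarray(density, float))

    # -- support / density -------------------------------------------------

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "uniform":
            return self.params  # type: ignore[return-value]
        if self.family == "point_mass":
            a0 = self.params[0]
            return (a0, a0)
        return (float(self.grid[0]), float(self.grid[-1]))  # type: ignore[index]

    def pdf(self, a: float | np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        if self.family == "uniform":
            low, high = self.params
            return np.where((a >= low) & (a <= high), 1.0 / (high - low), 0.0)
        if self.family == "point_mass":
            raise ValueError("point mass has no density function")
        out = np.interp(a, self.grid, self.density, left=0.0, right=0.0)
        lo, hi = self.support
        return np.where((a >= lo) & (a <= hi), out, 0.0)

    # -- moments -----------------------------------------------------------

    def moment(self, k: int) -> float:
        """Exact k-th raw moment ``<a^k>``."""
        if k < 0:
            raise ValueError("moment order must be >= 0")
        if self.family == "uniform":
            low, high = self.params
            return (high ** (k + 1) - low ** (k + 1)) / ((k + 1) * (high - low))
        if self.family == "point_mass":
            return self.params[0] ** k
        val, _ = _sciint.quad(lambda a: np.interp(a, self.grid, self.density) * a**k, *self.support, limit=200)
        return float(val)

    def moments(self, k_max: int) -> np.ndarray:
        return np.array([self.moment(k) for k in range(k_max + 1)])

    @property
    def mean(self) -> float:
        return self.moment(1)

    # -- sampling ----------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("sample size must be >= 1")
        if self.family == "uniform":
            low, high = self.params
            return rng.uniform(low, high, size=n)
        if self.family == "point_mass":
            return np.full(n, self.params[0])
        # inverse-CDF sampling on the tabulated grid
        cdf = _sciint.cumulative_trapezoid(self.density, self.grid, initial=0.0)
        cdf /= cdf[-1]
        return np.interp(rng.random(n), cdf, self.grid)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"family": self.family}
        if self.family == "tabulated":
            d["grid"] = np.asarray(self.grid).tolist()
            d["density"] = np.asarray(self.density).tolist()
        else:
            d["params"] = list(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ActivityDistribution":
        fam = d["family"]
        if fam == "tabulated":
            return cls.tabulated(d["grid"], d["density"])
        return cls(fam, tuple(d.get("params", ())))


@dataclass(frozen=True)
class TemporalNetConfig:
    """Size and wiring parameters of the activity-driven model."""

    N: int
    m: int
    delta: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if not (1 <= self.m <= self.N - 1):
            raise ValueError(f"links per activation m={self.m} must satisfy 1 <= m <= N-1={self.N - 1}")
        if self.delta < 1:
            raise ValueError("window length delta must be >= 1")


@dataclass(frozen=True)
class InstantaneousGraph:
    """One snapshot G(tau): a simple undirected graph on nodes 0..N-1."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int array, each row (u, v) with u < v
    step: int = 0

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass(frozen=True)
class IntegratedGraph:
    """Union network G_delta(t) of one delta-step window (simple graph).

    ``multiplicity`` is populated only when the window is built with
    ``multigraph=True``; it counts in how many snapshots each edge appeared.
    """

    n_nodes: int
    edges: np.ndarray
    window: tuple[int, int] = (0, 1)  # (t, delta)
    multiplicity: np.ndarray | None = None

    n_edges = InstantaneousGraph.n_edges
    degrees = InstantaneousGraph.degrees
    to_networkx = InstantaneousGraph.to_networkx


# ---------------------------------------------------------------------------
# generation


def sample_activities(dist: ActivityDistribution, N: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw N i.i.d. activity potentials from ``dist`` (deterministic per seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed)
    return dist.sample(N, rng)


def _draw_partners(active: np.ndarray, N: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Partners for each active node: m distinct draws from V \\ {u}.

    Rows with repeated partners are redrawn wholesale, which conditions the
    with-replacement draw on distinctness and hence is an exact uniform
    without-replacement sample.
    """
    k = active.size
    draws = rng.integers(0, N - 1, size=(k, m))
    draws += draws >= active[:, None]  # skip the self index
    if m > 1:
        bad = np.flatnonzero((np.sort(draws, axis=1)[:, 1:] == np.sort(draws, axis=1)[:, :-1]).any(axis=1))
        while bad.size:
            redraw = rng.integers(0, N - 1, size=(bad.size, m))
            redraw += redraw >= active[bad, None]
            draws[bad] = redraw
            dup = (np.sort(redraw, axis=1)[:, 1:] == np.sort(redraw, axis=1)[:, :-1]).any(axis=1)
            bad = bad[dup]
    return draws


def _snapshot_codes(activities: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """One snapshot as edge codes u*N+v (u < v), possibly with repeats."""
    N = activities.size
    active = np.flatnonzero(rng.random(N) < activities)
    if active.size == 0:
        return np.empty(0, dtype=np.int64)
    partners = _draw_partners(active, N, m, rng)
    u = np.repeat(active, m).astype(np.int64)
    v = partners.ravel().astype(np.int64)
    lo = np.minimum(u, v)
    hi = np.maximum(u, v)
    return lo * N + hi


def _codes_to_edges(codes: np.ndarray, N: int) -> np.ndarray:
    edges = np.empty((codes.size, 2), dtype=np.int64)
    edges[:, 0] = codes // N
    edges[:, 1] = codes % N
    return edges


def _check_activities(activities: np.ndarray) -> np.ndarray:
    activities = np.asarray(activities, dtype=float)
    if activities.ndim != 1 or activities.size < 2:
        raise ValueError("need a 1-d activity vector of length N >= 2")
    if np.any((activities < 0) | (activities > 1)):
        raise ValueError("activities must lie in [0, 1]")
    return activities


def generate_instantaneous(
    activities: np.ndarray, m: int, rng: np.random.Generator, step: int = 0
) -> InstantaneousGraph:
    """Generate one activity-driven snapshot.

    Each node u activates with probability ``activities[u]``; active nodes
    wire ``m`` edges to distinct uniformly random partners.  Coinciding edges
    from different initiators collapse (simple graph).
    """
    activities = _check_activities(activities)
    N = activities.size
    if not (1 <= m <= N - 1):
        raise ValueError(f"m={m} must satisfy 1 <= m <= N-1={N - 1}")
    codes = np.unique(_snapshot_codes(activities, m, rng))
    return InstantaneousGraph(N, _codes_to_edges(codes, N), step=step)


def integrate_window(
    activities: np.ndarray,
    m: int,
    delta: int,
    rng: np.random.Generator,
    t: int = 0,
    multigraph: bool = False,
) -> IntegratedGraph:
    """Union of ``delta`` fresh snapshots (edges of earlier windows are gone).

    With ``multigraph=True`` the edge multiplicities across the window's
    snapshots are reported alongside the simple edge set.
    """
    activities = _check_activities(activities)
    N = activities.size
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if not (1 <= m <= N - 1):
        raise ValueError(f"m={m} must satisfy 1 <= m <= N-1={N - 1}")
    chunks = []
    for _ in range(delta):
        # each snapshot's within-step duplicates collapse before counting
        chunks.append(np.unique(_snapshot_codes(activities, m, rng)))
    codes = np.concatenate(chunks) if chunks else np.empty(0, np.int64)
    if multigraph:
        uniq, counts = np.unique(codes, return_counts=True)
        return IntegratedGraph(N, _codes_to_edges(uniq, N), window=(t, delta), multiplicity=counts)
    uniq = np.unique(codes)
    return IntegratedGraph(N, _codes_to_edges(uniq, N), window=(t, delta))


# ---------------------------------------------------------------------------
# theory


def mean_degree_theory(
    a: float,
    dist: ActivityDistribution,
    m: int,
    delta: int,
    N: float | int | None = None,
) -> float:
    """Expected integrated-network degree of a node with activity ``a``.

    In the infinite-population limit this is ``(a + <a>) * m * delta``:
    ``a*m*delta`` initiated links plus ``<a>*m*delta`` received ones, with
    collision corrections vanishing as 1/N.  At finite ``N`` the initiated
    part saturates, ``N * (1 - exp(-a*m*delta/N))``, and received links only
    count when they miss the initiated set, giving the extra factor
    ``exp(-a*m*delta/N)`` on the received part.
    """
    if a < 0 or a > 1:
        raise ValueError("activity a must lie in [0, 1]")
    amd = a * m * delta
    mean_recv = dist.mean * m * delta
    if N is None or np.isinf(N):
        return amd + mean_recv
    N = float(N)
    if N < 2:
        raise ValueError("N must be >= 2 (or None for the infinite limit)")
    return N * (1.0 - np.exp(-amd / N)) + mean_recv * np.exp(-amd / N)


# ---------------------------------------------------------------------------
# i/o


def write_edgelist(graph: InstantaneousGraph | IntegratedGraph, path, header: dict | None = None) -> None:
    """Tab-separated two-column edge list preceded by a JSON header line."""
    meta = {"n_nodes": graph.n_nodes, "n_edges": graph.n_edges}
    if isinstance(graph, IntegratedGraph):
        meta["window"] = list(graph.window)
    if header:
        meta.update(header)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


def read_edgelist(path) -> IntegratedGraph:
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        rows = [tuple(map(int, line.split())) for line in fh if line.strip()]
    edges = np.array(rows, dtype=np.int64).reshape(-1, 2)
    n = int(meta.get("n_nodes", edges.max() + 1 if edges.size else 0))
    window = tuple(meta.get("window", (0, 1)))
    return IntegratedGraph(n, edges, window=window)
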