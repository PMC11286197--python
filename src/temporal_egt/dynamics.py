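"""Deterministic dynamics: replicator-like equations and the activity-moment
hierarchy.

Two deterministic descriptions of the same evolutionary process live here.

* The *replicator-like* equations ``dx_i/dt = x_i ((M x)_i - x.M.x)`` on the
  strategy simplex, with ``M`` either the raw game ``A`` (well-mixed) or the
  transformed game ``A' = alpha1*A + alpha2*B`` (temporal network).

* The *moment hierarchy* for ``I^k_i``, the population average of ``a^k``
  over carriers of strategy i (``I^0_i`` is the strategy frequency).  Its
  selection-free part,

      dI^k/dt = (-I^{k+1} - <a> I^k + <a^k> I^1 + <a^{k+1}> I^0) / 2,

  relaxes fast compared with the O(beta) frequency dynamics, pinning the
  system to the slow manifold ``I^k = <a^k> I^0``; substituting the manifold
  into the O(beta) terms reproduces the replicator-like equations with
  ``A'``.  The hierarchy here keeps the full O(beta) gain/loss terms so that
  this reduction can be verified numerically rather than assumed.

Two numerical routes to the hierarchy are provided.  ``moment_hierarchy_rhs``
evolves the truncated raw-moment vector directly, closing the orders above
``k_max`` either with the stationarity relation at the top order or with the
manifold values; truncation in raw-moment coordinates turns out to be
*linearly unstable* for broad activity densities once ``k_max`` is moderate
(spurious positive eigenvalues of order 0.1 appear for the near-uniform
density at ``k_max >= 4``), so this form is only trustworthy on or near the
manifold and over short horizons.  ``integrate_activity_density`` instead
evolves the joint density ``x_{a,i}`` on a Gauss-Legendre activity grid —
the equation one order up, of which the moment hierarchy is the exact
closure-free shadow — and is uniformly stable; its moments satisfy the
hierarchy to quadrature accuracy and it is the reference route for
relaxation and weak-selection consistency checks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .activity_net import ActivityDistribution
from .game_theory import PayoffMatrix, local_competition_matrix

__all__ = [
    "replicator_rhs",
    "replicator_jacobian",
    "Trajectory",
    "integrate_trajectory",
    "integrate_log_trajectory",
    "slow_manifold_moments",
    "moment_hierarchy_rhs",
    "integrate_moment_hierarchy",
    "ActivityGrid",
    "density_rhs",
    "density_moments",
    "manifold_density",
    "integrate_activity_density",
    "Classification",
    "FixedPointReport",
    "classify_fixed_point",
    "simplex_tangent_basis",
]


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, PayoffMatrix):
        return M.entries
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("dynamics matrix must be square")
    return M


def _check_simplex(x: np.ndarray, n: int, tol: float = 1e-8) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"state must have length {n}")
    if np.any(x < -tol) or abs(x.sum() - 1.0) > max(tol, 1e-8):
        raise ValueError(f"state {x} is not on the probability simplex")
    return x


def replicator_rhs(M, x) -> np.ndarray:
    """Velocity ``x_i ((Mx)_i - x.M.x)``; components sum to zero."""
    M = _as_matrix(M)
    x = _check_simplex(x, M.shape[0])
    fitness = M @ x
    return x * (fitness - x @ fitness)


def replicator_jacobian(M, x) -> np.ndarray:
    """Closed-form Jacobian of the replicator velocity field at x."""
    M = _as_matrix(M)
    x = np.asarray(x, dtype=float)
    f = M @ x
    phi = x @ f
    grad_phi = f + M.T @ x  # d(x.M.x)/dx_j
    J = np.diag(f - phi) + x[:, None] * (M - grad_phi[None, :])
    return J


def simplex_tangent_basis(n: int) -> np.ndarray:
    """Orthonormal (n, n-1) basis of the tangent space {v : sum v = 0}."""
    full = np.eye(n) - np.full((n, n), 1.0 / n)
    q, r = np.linalg.qr(full)
    return q[:, : n - 1]


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray  # shape (len(t), n)
    absorbed: bool = False
    absorbed_vertex: int | None = None
    max_simplex_drift: float = 0.0
    events: list = field(default_factory=list)

    @property
    def terminal(self) -> np.ndarray:
        return self.x[-1]


def integrate_trajectory(
    M,
    x0,
    t_end: float,
    tol: float | None = None,
    *,
    rtol: float = 1e-11,
    atol: float = 1e-13,
    t_eval: np.ndarray | None = None,
    method: str = "DOP853",
    mutation: float = 0.0,
    absorption_tol: float = 1e-6,
    stop_on_absorption: bool = False,
) -> Trajectory:
    """Adaptive integration of the replicator(-like) flow from x0 to t_end.

    The simplex is invariant analytically; numerically each sampled state is
    clipped at zero and renormalised, and the largest drift |sum x - 1| seen
    before renormalisation is reported.  ``mutation`` adds a uniform
    mutation term ``mutation * (1/n - x_i)`` (a stress test for structural
    stability of boundary attractors, not part of the baseline model).
    Vertex absorption within ``absorption_tol`` is recorded as an event and
    optionally terminates the run.
    """
    M = _as_matrix(M)
    n = M.shape[0]
    x0 = _check_simplex(x0, n)
    if tol is not None:
        rtol = tol

    if mutation:
        def rhs(_t, x):
            f = M @ x
            return x * (f - x @ f) + mutation * (1.0 / n - x)
    else:
        def rhs(_t, x):
            f = M @ x
            return x * (f - x @ f)

    events = None
    if stop_on_absorption:
        def near_vertex(_t, x):
            return np.max(x) - (1.0 - absorption_tol)

        near_vertex.terminal = True
        near_vertex.direction = 1.0
        events = [near_vertex]

    sol = solve_ivp(
        rhs, (0.0, float(t_end)), x0, method=method, rtol=rtol, atol=atol, t_eval=t_eval,
        events=events, dense_output=t_eval is None,
    )
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    xs = sol.y.T
    drift = float(np.max(np.abs(xs.sum(axis=1) - 1.0))) if xs.size else 0.0
    xs = np.clip(xs, 0.0, None)
    xs /= xs.sum(axis=1, keepdims=True)
    traj = Trajectory(sol.t, xs, max_simplex_drift=drift)
    xT = traj.terminal
    if np.max(xT) >= 1.0 - absorption_tol:
        traj.absorbed = True
        traj.absorbed_vertex = int(np.argmax(xT))
        traj.events.append(("absorbed", traj.t[-1], traj.absorbed_vertex))
    return traj


def integrate_log_trajectory(
    M,
    x0,
    t_end: float,
    *,
    rtol: float = 1e-11,
    atol: float = 1e-11,
    t_eval: np.ndarray | None = None,
    method: str = "DOP853",
) -> tuple[np.ndarray, np.ndarray]:
    """Replicator flow in log coordinates ``y_i = ln x_i``.

    Since ``dy_i/dt = (Mx)_i - x.M.x``, strategies approaching extinction
    simply drift to large negative ``y`` instead of underflowing, so relative
    accuracy of vanishing frequencies — and with it any conserved cross-ratio
    of frequencies — is preserved over arbitrarily deep boundary approaches.
    Requires an interior ``x0``.  Returns ``(t, y)`` with ``x = exp(y)``.
    """
    M = _as_matrix(M)
    n = M.shape[0]
    x0 = _check_simplex(x0, n)
    if np.any(x0 <= 0):
        raise ValueError("log-coordinate integration needs an interior start (all x0 > 0)")

    def rhs(_t, y):
        x = np.exp(y)
        f = M @ x
        return f - x @ f

    sol = solve_ivp(rhs, (0.0, float(t_end)), np.log(x0), method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"log-replicator integration failed: {sol.message}")
    return sol.t, sol.y.T


# ---------------------------------------------------------------------------
# moment hierarchy


def slow_manifold_moments(x, dist: ActivityDistribution, k: int) -> np.ndarray:
    """Equilibrium moments on the slow manifold: ``I^k_i = <a^k> x_i``."""
    x = np.asarray(x, dtype=float)
    return dist.moment(k) * x


class Closure(enum.Enum):
    SLOW_MANIFOLD_TOP = "slow-manifold-top"  # close via the stationarity relation at k_max
    TRUNCATE_TOP = "truncate-top"            # close with the manifold values <a^k> I^0


def _extend_moments(I: np.ndarray, mu: np.ndarray, k_max: int, closure: Closure) -> np.ndarray:
    """Append I^{k_max+1} and I^{k_max+2} columns according to the closure."""
    n = I.shape[0]
    ext = np.empty((n, k_max + 3))
    ext[:, : k_max + 1] = I
    if closure is Closure.TRUNCATE_TOP:
        ext[:, k_max + 1] = mu[k_max + 1] * I[:, 0]
        ext[:, k_max + 2] = mu[k_max + 2] * I[:, 0]
    else:
        # stationarity of the neutral flow at order k: I^{k+1} = <a^k> I^1 + <a^{k+1}> I^0 - <a> I^k
        ext[:, k_max + 1] = mu[k_max] * I[:, 1] + mu[k_max + 1] * I[:, 0] - mu[1] * I[:, k_max]
        ext[:, k_max + 2] = mu[k_max + 1] * I[:, 1] + mu[k_max + 2] * I[:, 0] - mu[1] * ext[:, k_max + 1]
    return ext


def moment_hierarchy_rhs(
    I: np.ndarray,
    dist: ActivityDistribution,
    game=None,
    *,
    m: int = 1,
    delta: int = 1,
    beta: float = 0.0,
    closure: Closure | str = Closure.SLOW_MANIFOLD_TOP,
    mu: np.ndarray | None = None,
) -> np.ndarray:
    """Time derivative of the moment table ``I`` (shape (n_strategies, k_max+1)).

    The selection-free part is exact.  The O(beta) part carries the four
    imitation gain/loss channels (active focal vs role-model-generated link,
    each in both directions) with the expected payoff of an activity-a
    player ``E(P_a,i) = ((a + <a>) m delta - 1) * sum_l a_il I^0_l + a_ij``,
    the last term being the game against the imitation partner itself.
    Orders above k_max are closed per ``closure``.
    """
    I = np.asarray(I, dtype=float)
    if I.ndim != 2:
        raise ValueError("moment table must be 2-d: (n_strategies, k_max+1)")
    closure = Closure(closure)
    n, kcols = I.shape
    k_max = kcols - 1
    if k_max < 1:
        raise ValueError("need k_max >= 1")
    if mu is None:
        mu = dist.moments(k_max + 2)
    ext = _extend_moments(I, mu, k_max, closure)

    ks = np.arange(k_max + 1)
    # neutral part; identically zero at k = 0 (frequencies move only at O(beta))
    out = 0.5 * (-ext[:, 1 : k_max + 2] - mu[1] * ext[:, : k_max + 1]
                 + mu[ks] * ext[:, 1:2] + mu[ks + 1] * ext[:, 0:1])

    if beta != 0.0:
        if game is None:
            raise ValueError("selection terms need a payoff matrix")
        A = game.entries if isinstance(game, PayoffMatrix) else np.asarray(game, float)
        if A.shape != (n, n):
            raise ValueError("payoff matrix size must match the number of strategies")
        B = local_competition_matrix(A)
        md = m * delta
        pi = A @ ext[:, 0]  # expected per-neighbour payoff of each strategy
        c0 = mu[1] * md - 1.0
        sel = np.zeros_like(out)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                cij = c0 * (pi[j] - pi[i]) - B[i, j]
                cji = c0 * (pi[i] - pi[j]) + B[i, j]
                Ii = ext[i]
                Ij = ext[j]
                for k in ks:
                    loss1 = md * (Ii[k + 1] * Ij[1] * pi[j] - Ii[k + 2] * Ij[0] * pi[i]) + Ii[k + 1] * Ij[0] * cij
                    loss2 = md * (Ii[k] * Ij[2] * pi[j] - Ii[k + 1] * Ij[1] * pi[i]) + Ii[k] * Ij[1] * cij
                    gain1 = md * (Ij[k + 1] * Ii[1] * pi[i] - Ij[k + 2] * Ii[0] * pi[j]) + Ij[k + 1] * Ii[0] * cji
                    gain2 = md * (Ij[k] * Ii[2] * pi[i] - Ij[k + 1] * Ii[1] * pi[j]) + Ij[k] * Ii[1] * cji
                    sel[i, k] += gain1 + gain2 - loss1 - loss2
        out += 0.25 * beta * sel
    return out


def integrate_moment_hierarchy(
    I0: np.ndarray,
    dist: ActivityDistribution,
    game=None,
    *,
    m: int = 1,
    delta: int = 1,
    beta: float = 0.0,
    t_end: float,
    closure: Closure | str = Closure.SLOW_MANIFOLD_TOP,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "DOP853",
):
    """Integrate the hierarchy; returns (t, I[t] array of shape (nt, n, k_max+1))."""
    I0 = np.asarray(I0, dtype=float)
    n, kcols = I0.shape
    mu = dist.moments(kcols + 1)
    closure = Closure(closure)

    def rhs(_t, y):
        return moment_hierarchy_rhs(
            y.reshape(n, kcols), dist, game, m=m, delta=delta, beta=beta, closure=closure, mu=mu
        ).ravel()

    sol = solve_ivp(rhs, (0.0, float(t_end)), I0.ravel(), method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"moment-hierarchy integration failed: {sol.message}")
    return sol.t, sol.y.T.reshape(-1, n, kcols)


# ---------------------------------------------------------------------------
# activity-density route (closure-free)


@dataclass(frozen=True)
class ActivityGrid:
    """Gauss-Legendre quadrature grid on the support of an activity density."""

    nodes: np.ndarray
    weights: np.ndarray
    f: np.ndarray  # density values at the nodes

    @classmethod
    def from_distribution(cls, dist: ActivityDistribution, size: int = 40) -> "ActivityGrid":
        lo, hi = dist.support
        if lo >= hi:
            raise ValueError("activity-density integration needs a continuous distribution")
        x, w = np.polynomial.legendre.leggauss(size)
        nodes = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        weights = 0.5 * (hi - lo) * w
        return cls(nodes, weights, dist.pdf(nodes))

    def moment(self, k: int) -> float:
        return float(self.weights @ (self.f * self.nodes**k))


def manifold_density(x, grid: ActivityGrid) -> np.ndarray:
    """Joint density on the slow manifold: ``x_{a,i} = f(a) * x_i``."""
    x = np.asarray(x, dtype=float)
    return x[:, None] * grid.f[None, :]


def density_moments(Phi: np.ndarray, grid: ActivityGrid, k_max: int) -> np.ndarray:
    """Moment table I^k_i = integral of a^k x_{a,i} da, shape (n, k_max+1)."""
    powers = grid.nodes[:, None] ** np.arange(k_max + 1)[None, :]
    return Phi @ (grid.weights[:, None] * powers)


def density_rhs(
    Phi: np.ndarray,
    grid: ActivityGrid,
    game=None,
    *,
    m: int = 1,
    delta: int = 1,
    beta: float = 0.0,
) -> np.ndarray:
    """Mean-field flow of the joint density x_{a,i} of (activity, strategy).

    A focal (a, j) individual imitates a model (a', i) with contact weight
    ``a + a'`` (own activations plus links generated by the model) at the
    Fermi probability linearised in beta, with expected accumulated payoffs
    ``E(P_a,i) = ((a + <a>) m delta - 1) pi_i + a_ij`` (``pi_i`` the mean
    per-neighbour payoff of strategy i, ``a_ij`` the game against the
    imitation partner).  Taking a^k moments of this flow yields the moment
    hierarchy exactly, with no truncation.
    """
    Phi = np.asarray(Phi, dtype=float)
    n, Q = Phi.shape
    aq, wq = grid.nodes, grid.weights
    I0 = Phi @ wq
    I1 = Phi @ (wq * aq)
    tot = Phi.sum(axis=0)
    T0, T1 = I0.sum(), I1.sum()
    # neutral imitation: gain from all strategies at activity a, loss to the field
    out = 0.5 * ((aq[None, :] * I0[:, None] + I1[:, None]) * tot[None, :] - Phi * (aq * T0 + T1)[None, :])
    if beta != 0.0:
        if game is None:
            raise ValueError("selection terms need a payoff matrix")
        A = game.entries if isinstance(game, PayoffMatrix) else np.asarray(game, float)
        B = local_competition_matrix(A)
        md = m * delta
        mu1 = grid.moment(1)
        I2 = Phi @ (wq * aq * aq)
        pi = A @ I0
        Eb = ((aq[None, :] + mu1) * md - 1.0) * pi[:, None]  # payoff sans the partner term
        J0 = ((I1 + mu1 * I0) * md - I0) * pi  # integral of phi_s * Eb_s
        J1 = ((I2 + mu1 * I1) * md - I1) * pi  # integral of a * phi_s * Eb_s
        sel = np.zeros_like(Phi)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                ci = aq * I0[i] + I1[i]
                cj = aq * I0[j] + I1[j]
                gain = Phi[j] * ((aq * J0[i] + J1[i]) + ci * (B[i, j] - Eb[j]))
                loss = Phi[i] * ((aq * J0[j] + J1[j]) + cj * (B[j, i] - Eb[i]))
                sel[i] += gain - loss
        out += 0.25 * beta * sel
    return out


def integrate_activity_density(
    Phi0: np.ndarray,
    grid: ActivityGrid,
    game=None,
    *,
    m: int = 1,
    delta: int = 1,
    beta: float = 0.0,
    t_end: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-12,
    atol: float = 1e-14,
    method: str = "DOP853",
):
    """Integrate the joint-density flow; returns (t, Phi[t] of shape (nt, n, Q))."""
    Phi0 = np.asarray(Phi0, dtype=float)
    n, Q = Phi0.shape

    def rhs(_t, y):
        return density_rhs(y.reshape(n, Q), grid, game, m=m, delta=delta, beta=beta).ravel()

    sol = solve_ivp(rhs, (0.0, float(t_end)), Phi0.ravel(), method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"activity-density integration failed: {sol.message}")
    return sol.t, sol.y.T.reshape(-1, n, Q)


# ---------------------------------------------------------------------------
# fixed points


class Classification(enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    SADDLE = "saddle"
    NEUTRAL = "non-isolated/neutral-direction"
    UNDECIDED = "undecided"


@dataclass(frozen=True)
class FixedPointReport:
    location: np.ndarray
    eigenvalues: np.ndarray  # tangent-space spectrum, n-1 values
    classification: Classification
    residual: float
    tol: float

    @property
    def n_unstable(self) -> int:
        return int(np.sum(self.eigenvalues.real > self.tol))

    @property
    def n_stable(self) -> int:
        return int(np.sum(self.eigenvalues.real < -self.tol))

    @property
    def n_neutral(self) -> int:
        return int(np.sum(np.abs(self.eigenvalues.real) <= self.tol))

    @property
    def has_unstable_direction(self) -> bool:
        return self.n_unstable > 0

    @property
    def attracting(self) -> bool:
        return self.n_unstable == 0 and self.n_neutral == 0


def classify_fixed_point(M, x_star, tol: float = 1e-7, residual_tol: float = 1e-8) -> FixedPointReport:
    """Linear stability of a rest point of the replicator(-like) flow.

    The Jacobian is evaluated in closed form and projected onto the
    (n-1)-dimensional tangent space of the simplex (the all-ones direction
    is an artefact of the embedding).  Eigenvalue real parts beyond +-tol
    count as unstable/stable directions; a zero direction with no unstable
    one marks a non-isolated rest point (e.g. a line of equilibria).
    """
    M = _as_matrix(M)
    n = M.shape[0]
    x_star = _check_simplex(x_star, n)
    res = float(np.linalg.norm(replicator_rhs(M, x_star)))
    if res > residual_tol:
        raise ValueError(f"x_star is not a fixed point: |rhs| = {res:.3e} > {residual_tol:.1e}")
    E = simplex_tangent_basis(n)
    Jt = E.T @ replicator_jacobian(M, x_star) @ E
    eig = np.linalg.eigvals(Jt)
    re = eig.real
    n_pos = int(np.sum(re > tol))
    n_neg = int(np.sum(re < -tol))
    n_zero = (n - 1) - n_pos - n_neg
    if n_zero == 0:
        if n_pos == 0:
            cls = Classification.STABLE
        elif n_neg == 0:
            cls = Classification.UNSTABLE
        else:
            cls = Classification.SADDLE
    elif n_pos > 0:
        cls = Classification.UNSTABLE
    elif n_neg > 0:
        cls = Classification.NEUTRAL
    else:
        cls = Classification.UNDECIDED
    return FixedPointReport(x_star, eig, cls, res, tol)
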