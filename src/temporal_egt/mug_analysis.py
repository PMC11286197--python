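"""Fairness in the mini-ultimatum game (MUG) on temporal networks.

With strategies R = [l,l], G = [h,l], F = [h,h], I = [l,h] (offer,
acceptance-threshold pairs restricted to a low level ``l`` and a high level
``h``), the temporal-network replicator-like dynamics with transformed game
``A' = alpha1*A + alpha2*B`` exhibits:

* a critical offer level ``l* = alpha2 / (alpha1 + 2*alpha2)`` below which
  the reasonable strategy R loses evolutionary stability (its binding rival
  is the immoral strategy I);
* closed-form rest points on the R-F and G-I edges and a stable/unstable
  split point on the G-F line of rest points, all with explicit existence
  conditions;
* a conserved quantity ``K = (x_R x_F) / (x_G x_I)`` in the interior, which
  foliates the state space into invariant surfaces and rules out interior
  rest points.

The well-mixed taxonomy is the special case ``(alpha1, alpha2) = (1, 0)``
of every operation here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import FixedPointReport, classify_fixed_point, replicator_rhs
from .game_theory import MUG_LABELS, Verdict, ess_temporal, mug_matrix, transformed_matrix

__all__ = [
    "critical_offer",
    "EdgeFixedPoint",
    "edge_fixed_points",
    "constant_of_motion",
    "phase_diagram",
    "PhaseVerdict",
    "mug_transformed",
]

_R, _G, _F, _I = range(4)


def mug_transformed(h: float, l: float, alpha1: float, alpha2: float) -> np.ndarray:
    """Transformed MUG payoff matrix A' = alpha1*A + alpha2*B."""
    return transformed_matrix(mug_matrix(h, l), alpha1, alpha2).A_prime


def critical_offer(alpha1: float, alpha2: float) -> float:
    """Critical low-offer level ``alpha2 / (alpha1 + 2*alpha2)``.

    R is evolutionarily unstable on the temporal network iff the game's low
    offer l falls strictly below this threshold.  At alpha2 = 0 (well mixed)
    the threshold is 0 and R is never destabilised by this mechanism; as
    alpha1 -> 0 (pure local competition) it approaches 1/2.
    """
    den = alpha1 + 2.0 * alpha2
    if den <= 0:
        raise ValueError("alpha1 + 2*alpha2 must be positive")
    return alpha2 / den


@dataclass(frozen=True)
class EdgeFixedPoint:
    edge: str  # e.g. "R-F"
    location: np.ndarray
    exists: bool
    stability: FixedPointReport | None


def _interior_on_edge(x: np.ndarray, idx_a: int, idx_b: int) -> bool:
    return bool(0.0 < x[idx_a] < 1.0 and 0.0 < x[idx_b] < 1.0)


def edge_fixed_points(h: float, l: float, alpha1: float, alpha2: float) -> list[EdgeFixedPoint]:
    """Closed-form rest points on the edges of the MUG simplex.

    Returns the interior R-F point, the interior G-I point, and the endpoint
    of the stable segment of the G-F line of rest points.  Existence is
    decided by strict interior membership of the closed-form coordinates;
    non-existent points are returned with ``exists=False`` (and no stability
    report).  At ``alpha2 = 0`` the R-F point reduces to the classical
    well-mixed location [1-h, 0, h, 0].
    """
    if not (0.0 < l < h < 0.5):
        raise ValueError(f"offers must satisfy 0 < l < h < 1/2, got l={l}, h={h}")
    if alpha1 <= 0:
        raise ValueError("alpha1 must be positive for the closed forms")
    A_prime = mug_transformed(h, l, alpha1, alpha2)
    out: list[EdgeFixedPoint] = []

    def report(x: np.ndarray) -> FixedPointReport:
        return classify_fixed_point(A_prime, x, residual_tol=1e-10)

    # R-F edge: bistability splitter between the reasonable and fair vertices
    x_rf = np.array(
        [(alpha1 * (1.0 - h) + alpha2 * (1.0 - 2.0 * h)) / alpha1, 0.0,
         (alpha1 * h - alpha2 * (1.0 - 2.0 * h)) / alpha1, 0.0]
    )
    exists = _interior_on_edge(x_rf, _R, _F)
    out.append(EdgeFixedPoint("R-F", x_rf, exists, report(x_rf) if exists else None))

    # G-I edge interior point
    x_gi = np.array(
        [0.0, (alpha1 * (1.0 - h + l) - 2.0 * alpha2 * (h - l)) / alpha1, 0.0,
         (alpha1 * (h - l) + 2.0 * alpha2 * (h - l)) / alpha1]
    )
    exists = _interior_on_edge(x_gi, _G, _I)
    out.append(EdgeFixedPoint("G-I", x_gi, exists, report(x_gi) if exists else None))

    # endpoint of the stable segment of the G-F rest-point line
    D = alpha1 * (1.0 - l) + alpha2 * (1.0 - 2.0 * l)
    x_gf = np.array(
        [0.0, (alpha1 * (1.0 - h) + alpha2 * (1.0 - 2.0 * h)) / D,
         (h - l) * (alpha1 + 2.0 * alpha2) / D, 0.0]
    )
    exists = _interior_on_edge(x_gf, _G, _F)
    out.append(EdgeFixedPoint("G-F", x_gf, exists, report(x_gf) if exists else None))
    return out


def constant_of_motion(x) -> float:
    """Conserved cross-ratio ``K = (x_R x_F) / (x_G x_I)`` of an interior state."""
    x = np.asarray(x, dtype=float)
    if x.shape != (4,):
        raise ValueError("MUG state must have 4 components (R, G, F, I)")
    if np.any(x <= 0.0):
        raise ValueError("constant of motion is defined only for interior states (all components > 0)")
    return float((x[_R] * x[_F]) / (x[_G] * x[_I]))


class PhaseVerdict(enum.Enum):
    R_STABLE = "R-stable"
    R_UNSTABLE = "R-unstable"
    BOUNDARY = "boundary/undecided"


def _representative_h(l: float) -> float:
    return 0.5 * (l + 0.5)


def phase_diagram(
    alpha_ratio_grid, l_grid, *, check_h_independence: bool = False
) -> pd.DataFrame:
    """Evolutionary stability of R over a grid of (alpha2/alpha1, l).

    Each cell is classified by the temporal ESS test on the MUG with a
    representative high offer h in (l, 1/2); the verdict depends only on
    whether l clears the critical offer, never on the choice of h, which can
    be spot-checked per cell with ``check_h_independence``.  Cells exactly on
    the critical line are reported as boundary/undecided.
    """
    rows = []
    for ratio in np.asarray(alpha_ratio_grid, dtype=float):
        if ratio <= 0:
            raise ValueError("alpha2/alpha1 grid must be positive")
        thr = critical_offer(1.0, ratio)
        for l in np.asarray(l_grid, dtype=float):
            if not (0.0 < l < 0.5):
                raise ValueError("l grid must lie in (0, 1/2)")
            h = _representative_h(l)
            verdict, _ = ess_temporal(mug_matrix(h, l), 1.0, ratio, _R)
            cell = {
                Verdict.ESS: PhaseVerdict.R_STABLE,
                Verdict.NOT_ESS: PhaseVerdict.R_UNSTABLE,
                Verdict.UNDECIDED: PhaseVerdict.BOUNDARY,
            }[verdict]
            if check_h_independence:
                h2 = l + 0.25 * (0.5 - l)
                v2, _ = ess_temporal(mug_matrix(h2, l), 1.0, ratio, _R)
                if v2 is not verdict:
                    raise AssertionError(f"verdict depends on representative h at ratio={ratio}, l={l}")
            rows.append({"alpha_ratio": ratio, "l": l, "critical_offer": thr, "verdict": cell.value})
    return pd.DataFrame(rows)
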