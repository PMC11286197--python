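"""Payoff-matrix algebra for games on temporal networks.

Under weak selection, an activity-driven temporal population structure
re-scales an n-by-n game ``A`` into ``A' = alpha1*A + alpha2*B`` where
``B = A - A^T`` is the antisymmetric *local-competition* matrix (the
zero-sum head-to-head part of the game) and the weights

    alpha1 = beta * (3*m*delta*<a>^2 + m*delta*<a^2> - 2*<a>) / 2
    alpha2 = beta * <a>

depend only on selection intensity ``beta``, the wiring parameters
``m, delta`` and the first two activity moments.  Only the normalised weight
``alpha2 / (alpha1 + alpha2) = 2<a> / (m*delta*(3<a>^2 + <a^2>))`` matters
for phase portraits, since a positive rescaling of the payoff matrix only
rescales time.

The module also hosts the evolutionary-stability tests (well-mixed and
temporal-network variants) and the mini-ultimatum game constructor.
"""

from __future__ import annotations

import csv
import enum
import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .activity_net import ActivityDistribution

__all__ = [
    "PayoffMatrix",
    "TransformedGame",
    "SelectionWeights",
    "Verdict",
    "RivalReport",
    "local_competition_matrix",
    "selection_weights",
    "transformed_matrix",
    "ess_well_mixed",
    "ess_temporal",
    "mug_matrix",
    "MUG_LABELS",
]

MUG_LABELS = ("R", "G", "F", "I")


@dataclass(frozen=True)
class PayoffMatrix:
    """A symmetric-role pairwise game: ``entries[i, j]`` pays row strategy i
    when matched against column strategy j."""

    labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValueError("payoff matrix must be square")
        if entries.shape[0] < 2:
            raise ValueError("need at least two strategies")
        if not np.all(np.isfinite(entries)):
            raise ValueError("payoff entries must be finite")
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != entries.shape[0]:
            raise ValueError("label count must match matrix size")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_entries(cls, entries, labels: Sequence[str] | None = None) -> "PayoffMatrix":
        entries = np.asarray(entries, dtype=float)
        if labels is None:
            labels = [f"s{i + 1}" for i in range(entries.shape[0])]
        return cls(tuple(labels), entries)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def payoff(self, row: str, col: str) -> float:
        return float(self.entries[self.index(row), self.index(col)])

    # -- i/o ---------------------------------------------------------------

    def to_json(self, path=None) -> str:
        s = json.dumps({"labels": list(self.labels), "rows": self.entries.tolist()}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, src) -> "PayoffMatrix":
        if isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(tuple(d["labels"]), np.asarray(d["rows"], float))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([""] + list(self.labels))
            for lab, row in zip(self.labels, self.entries):
                w.writerow([lab] + [repr(float(v)) for v in row])

    @classmethod
    def from_csv(cls, path) -> "PayoffMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        labels = tuple(rows[0][1:])
        entries = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        return cls(labels, entries)


def _as_array(game) -> np.ndarray:
    if isinstance(game, PayoffMatrix):
        return game.entries
    a = np.asarray(game, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("payoff matrix must be square")
    return a


def local_competition_matrix(game) -> np.ndarray:
    """Antisymmetric matrix ``b_ij = a_ij - a_ji`` of head-to-head payoff
    differences; satisfies ``x.B.x = 0`` for every mixed state x."""
    a = _as_array(game)
    return a - a.T


@dataclass(frozen=True)
class SelectionWeights:
    alpha1: float
    alpha2: float
    alpha2_norm: float

    def __iter__(self):
        return iter((self.alpha1, self.alpha2, self.alpha2_norm))


def selection_weights(beta: float, m: int, delta: int, dist: ActivityDistribution) -> SelectionWeights:
    """Weights (alpha1, alpha2) of A and B in the transformed game, plus the
    normalised weight alpha2/(alpha1+alpha2).

    The normalised weight is also computed from its closed form
    ``2<a>/(m*delta*(3<a>^2+<a^2>))`` and the two are cross-checked.
    """
    if beta < 0:
        raise ValueError("selection intensity beta must be >= 0")
    mu1 = dist.moment(1)
    mu2 = dist.moment(2)
    md = m * delta
    alpha1 = beta * (3.0 * md * mu1**2 + md * mu2 - 2.0 * mu1) / 2.0
    alpha2 = beta * mu1
    closed = 2.0 * mu1 / (md * (3.0 * mu1**2 + mu2))
    if beta == 0.0 or alpha1 + alpha2 == 0.0:
        warnings.warn("alpha1 + alpha2 = 0 (beta = 0?); normalised weight undefined", RuntimeWarning)
        return SelectionWeights(alpha1, alpha2, float("nan"))
    norm = alpha2 / (alpha1 + alpha2)
    if abs(norm - closed) > 1e-10 * max(1.0, abs(closed)):
        raise AssertionError(f"normalised-weight cross-check failed: {norm} vs {closed}")
    return SelectionWeights(alpha1, alpha2, norm)


@dataclass(frozen=True)
class TransformedGame:
    """The rescaled game A' = alpha1*A + alpha2*B driving the replicator-like
    dynamics on the temporal network."""

    base: PayoffMatrix
    alpha1: float
    alpha2: float
    B: np.ndarray
    A_prime: np.ndarray

    @property
    def alpha2_norm(self) -> float:
        tot = self.alpha1 + self.alpha2
        return self.alpha2 / tot if tot != 0 else float("nan")


def transformed_matrix(game, alpha1: float, alpha2: float) -> TransformedGame:
    """Build A' entrywise: off-diagonal ``(alpha1+alpha2)*a_ij - alpha2*a_ji``,
    diagonal ``alpha1*a_ii`` — identically equal to alpha1*A + alpha2*B."""
    pm = game if isinstance(game, PayoffMatrix) else PayoffMatrix.from_entries(game)
    a = pm.entries
    b = local_competition_matrix(a)
    a_prime = (alpha1 + alpha2) * a - alpha2 * a.T
    np.fill_diagonal(a_prime, alpha1 * np.diag(a))
    return TransformedGame(pm, float(alpha1), float(alpha2), b, a_prime)


class Verdict(enum.Enum):
    ESS = "ESS"
    NOT_ESS = "not-ESS"
    UNDECIDED = "undecided"  # some rival sits exactly on the ungeneric equality

    def __bool__(self) -> bool:
        return self is Verdict.ESS


@dataclass(frozen=True)
class RivalReport:
    rival: int
    margin: float  # >0 favours the resident
    note: str = ""


def ess_well_mixed(game, i: int) -> tuple[bool, list[RivalReport]]:
    """Classical ESS test for strategy i in a well-mixed population:
    for every rival j, either a_ii > a_ji, or a_ii = a_ji and a_ij > a_jj."""
    a = _as_array(game)
    reports: list[RivalReport] = []
    ok = True
    for j in range(a.shape[0]):
        if j == i:
            continue
        first = a[i, i] - a[j, i]
        if first > 0:
            reports.append(RivalReport(j, first, "strict first-order advantage"))
        elif first == 0 and a[i, j] - a[j, j] > 0:
            reports.append(RivalReport(j, a[i, j] - a[j, j], "neutral first order, strict second order"))
        else:
            ok = False
            reports.append(RivalReport(j, min(first, a[i, j] - a[j, j]), "invadable"))
    return ok, reports


def ess_temporal(
    game, alpha1: float, alpha2: float, i: int, tol: float = 0.0
) -> tuple[Verdict, list[RivalReport]]:
    """ESS test on the temporal network: resident i resists rival j when
    ``alpha1*a_ii + alpha2*a_ij > (alpha1+alpha2)*a_ji``.

    An exact (within ``tol``) equality for some rival is the ungeneric case;
    the verdict is then UNDECIDED rather than a silently forced boolean.
    """
    a = _as_array(game)
    reports: list[RivalReport] = []
    verdict = Verdict.ESS
    for j in range(a.shape[0]):
        if j == i:
            continue
        margin = alpha1 * a[i, i] + alpha2 * a[i, j] - (alpha1 + alpha2) * a[j, i]
        if abs(margin) <= tol:
            reports.append(RivalReport(j, margin, "ungeneric equality"))
            if verdict is Verdict.ESS:
                verdict = Verdict.UNDECIDED
        elif margin > 0:
            reports.append(RivalReport(j, margin))
        else:
            reports.append(RivalReport(j, margin, "invadable"))
            verdict = Verdict.NOT_ESS
    return verdict, reports


def mug_matrix(h: float, l: float) -> PayoffMatrix:
    """Mini-ultimatum game with offer levels low ``l`` and high ``h``,
    ``0 < l < h < 1/2``.

    A strategy is (offer, acceptance threshold): R = [l, l] (reasonable),
    G = [h, l] (generous), F = [h, h] (fair), I = [l, h] (immoral).  Each
    pairing is played in both roles, proposer and responder; a proposal below
    the responder's threshold pays both players nothing in that role.
    """
    if not (0.0 < l < h < 0.5):
        raise ValueError(f"offers must satisfy 0 < l < h < 1/2, got l={l}, h={h}")
    entries = np.array(
        [
            [1.0, 1.0 - l + h, h, l],
            [1.0 - h + l, 1.0, 1.0, 1.0 - h + l],
            [1.0 - h, 1.0, 1.0, 1.0 - h],
            [1.0 - l, 1.0 - l + h, h, 0.0],
        ]
    )
    return PayoffMatrix(MUG_LABELS, entries)
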