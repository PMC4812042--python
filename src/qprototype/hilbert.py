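"""Complex Hilbert-space model of two concepts and their disjunction.

Given per-item collapse probabilities mu_k(A), mu_k(B), mu_k(A or B) for two
concepts A and B over n items, the model represents each concept by a unit
vector in C^(n+1) and the disjunction by their equal-weight superposition
(|A> + |B>)/sqrt(2).  The measured disjunction probability then decomposes
as a classical average plus an interference term:

    mu_k(A or B) = (mu_k(A) + mu_k(B))/2
                   + c_k * sqrt(mu_k(A) mu_k(B)) * cos(phi_k)

where phi_k is the interference phase of item k and c_k in (0, 1] the
overlap of the item's two basis directions.  The construction fixes the
phases from the data (arccos of the normalized interference), assigns phase
signs by a greedy partial-sum scheme that enforces the sine-sum
orthogonality constraint <A|B> = 0, and tunes a single overlap c_m (for the
item with the largest interference budget lambda_k) to close the remaining
sine-sum residual.  All other c_k are 1, which keeps the space at n+1
complex dimensions: every item spans one basis direction except the rank-1
item, which spans two.

The estimator :class:`ConceptDisjunctionHilbert` exposes the construction in
scikit-learn style (``fit`` on an (n, 3) probability table, fitted
attributes with trailing underscores, ``predict`` returning the
reconstructed disjunction column); the module-level functions are thin
wrappers for one-off use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .membership import (
    MembershipRecord,
    MembershipTable,
    validate_normalization,
    DEFAULT_NORMALIZATION_TOL,
)

__all__ = [
    "InfeasibleModelError",
    "ItemAngles",
    "PartialSumTrace",
    "ConceptVector",
    "DisjunctionModel",
    "OrthogonalityReport",
    "ConceptDisjunctionHilbert",
    "lambda_of",
    "phase_of",
    "rank_and_sign",
    "c_m_of",
    "assemble_model",
    "reconstruct_disjunction",
    "verify_orthogonality",
]

# Relative slack absorbing float round-off at the arccos/sqrt domain edge;
# genuine infeasibility (|interference| > c*sqrt(mu_A mu_B)) is orders of
# magnitude larger on any data worth modeling.
_EDGE_EPS = 1e-12


class InfeasibleModelError(ValueError):
    """The Hilbert construction has no solution for the named items."""

    def __init__(self, message: str, items: Sequence[str] = ()):
        super().__init__(message)
        self.items = list(items)


@dataclass(frozen=True)
class ItemAngles:
    """Fitted interference parameters of one item."""

    item: str
    lambda_k: float
    rank: int            # 1..n in descending-lambda order
    epsilon: int         # phase sign, +1 or -1
    phi_deg: float       # signed interference phase, degrees
    c: float             # basis overlap; 1 for all items except rank 1


@dataclass(frozen=True)
class PartialSumTrace:
    """Record of the greedy sign scheme over the descending-lambda order.

    ``steps`` holds one ``(rank, item_index, lambda, epsilon, running_sum)``
    tuple per item; ``epsilon`` is re-indexed to the original item order.
    Every running sum is non-negative by construction.
    """

    steps: tuple[tuple[int, int, float, int, float], ...]
    epsilon: np.ndarray
    order: np.ndarray    # item indices, descending lambda
    final_sum: float


@dataclass(frozen=True)
class ConceptVector:
    """Unit vector in C^(n+1), stored as per-coordinate modulus and phase.

    ``norm_tol`` bounds the allowed deviation of the squared norm from one:
    exactly normalized probability columns give unit norm to machine
    precision, while 4-decimal printed columns can be off by a few 1e-4.
    """

    moduli: np.ndarray
    phases_deg: np.ndarray
    norm_tol: float = 1e-9

    def __post_init__(self) -> None:
        norm2 = float(np.sum(self.moduli**2))
        if abs(norm2 - 1.0) > self.norm_tol:
            raise ValueError(f"concept vector not unit norm: |v|^2 = {norm2!r}")

    @property
    def complex(self) -> np.ndarray:
        return self.moduli * np.exp(1j * np.radians(self.phases_deg))

    @property
    def dimension(self) -> int:
        return self.moduli.size


class OrthogonalityReport(NamedTuple):
    cosine_residual: float
    sine_residual: float
    overlap_abs: float


@dataclass
class DisjunctionModel:
    """Assembled Hilbert model: per-item angles, trace, and concept vectors."""

    table: MembershipTable
    angles: list[ItemAngles]
    trace: PartialSumTrace
    m_index: int
    c_m: float
    vector_A: ConceptVector
    vector_B: ConceptVector

    @property
    def lambda_(self) -> np.ndarray:
        return np.array([a.lambda_k for a in self.angles])

    @property
    def phi_deg(self) -> np.ndarray:
        return np.array([a.phi_deg for a in self.angles])

    @property
    def epsilon(self) -> np.ndarray:
        return np.array([a.epsilon for a in self.angles])

    @property
    def c(self) -> np.ndarray:
        return np.array([a.c for a in self.angles])

    @property
    def superposition(self) -> np.ndarray:
        """Normalized superposition state (|A> + |B>)/sqrt(2)."""
        return (self.vector_A.complex + self.vector_B.complex) / math.sqrt(2.0)

    def reconstruct(self) -> np.ndarray:
        """Disjunction probabilities from the interference formula."""
        mu_A, mu_B = self.table.mu_A, self.table.mu_B
        return 0.5 * (mu_A + mu_B) + self.c * np.sqrt(mu_A * mu_B) * np.cos(
            np.radians(self.phi_deg)
        )

    def reconstruct_from_state(self) -> np.ndarray:
        """Disjunction probabilities as <psi|M_k|psi> on the superposition.

        Item-k projector M_k covers coordinate k, plus the extra (n+1)-th
        coordinate for the rank-1 item.  Agrees with :meth:`reconstruct` to
        machine precision; kept as an internal consistency route.
        """
        psi = self.superposition
        probs = np.abs(psi[:-1]) ** 2
        probs[self.m_index] += abs(psi[-1]) ** 2
        return probs

    def to_dict(self) -> dict:
        return {
            "n_items": len(self.table),
            "items": [
                {
                    "item": a.item,
                    "lambda": a.lambda_k,
                    "rank": a.rank,
                    "epsilon": a.epsilon,
                    "phi_deg": a.phi_deg,
                    "c": a.c,
                }
                for a in self.angles
            ],
            "final_partial_sum": self.trace.final_sum,
            "c_m": self.c_m,
            "m_item": self.angles[self.m_index].item,
            "vector_A": {
                "modulus": self.vector_A.moduli.tolist(),
                "phase_deg": self.vector_A.phases_deg.tolist(),
            },
            "vector_B": {
                "modulus": self.vector_B.moduli.tolist(),
                "phase_deg": self.vector_B.phases_deg.tolist(),
            },
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _interference_parts(mu_A, mu_B, mu_AorB):
    product = np.asarray(mu_A, dtype=float) * np.asarray(mu_B, dtype=float)
    deviation = np.asarray(mu_AorB, dtype=float) - 0.5 * (
        np.asarray(mu_A, dtype=float) + np.asarray(mu_B, dtype=float)
    )
    return product, deviation


def lambda_of(record: MembershipRecord) -> float:
    """Interference budget lambda_k = sqrt(mu_A mu_B - interference^2).

    This is the largest interference magnitude the item can carry at unit
    basis overlap (c_k = 1).
    """
    product, deviation = _interference_parts(record.mu_A, record.mu_B, record.mu_AorB)
    if product <= 0:
        raise InfeasibleModelError(
            f"item {record.item!r} has mu_A*mu_B = 0: phase undefined", [record.item]
        )
    radicand = product - deviation**2
    if radicand < -_EDGE_EPS * product:
        raise InfeasibleModelError(
            f"item {record.item!r}: |interference| {abs(deviation):.6g} exceeds "
            f"sqrt(mu_A mu_B) {math.sqrt(product):.6g}; no phase exists",
            [record.item],
        )
    return math.sqrt(max(radicand, 0.0))


def phase_of(record: MembershipRecord, c_k: float = 1.0, epsilon_k: int = 1) -> float:
    """Signed interference phase in degrees.

    phi_k = epsilon_k * arccos[(mu_AorB - (mu_A+mu_B)/2) / (c_k sqrt(mu_A mu_B))].
    """
    if not (0.0 < c_k <= 1.0):
        raise ValueError(f"c_k must lie in (0, 1], got {c_k}")
    if epsilon_k not in (1, -1):
        raise ValueError("epsilon_k must be +1 or -1")
    product, deviation = _interference_parts(record.mu_A, record.mu_B, record.mu_AorB)
    if product <= 0:
        raise InfeasibleModelError(
            f"item {record.item!r} has mu_A*mu_B = 0: phase undefined", [record.item]
        )
    arg = deviation / (c_k * math.sqrt(product))
    if abs(arg) > 1.0 + _EDGE_EPS:
        raise InfeasibleModelError(
            f"item {record.item!r}: cosine argument {arg:.6g} outside [-1, 1]",
            [record.item],
        )
    return epsilon_k * math.degrees(math.acos(max(-1.0, min(1.0, arg))))


def rank_and_sign(lambdas: Sequence[float]) -> PartialSumTrace:
    """Greedy phase-sign assignment over the descending-lambda order.

    Starting from the largest lambda with sign +1, each next lambda is
    subtracted when the running sum stays non-negative and added otherwise,
    keeping every partial sum as small as possible but >= 0.  Ties in the
    ranking are broken by original item order.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size == 0:
        raise ValueError("empty lambda vector")
    if np.any(lam < 0):
        raise ValueError("lambda values must be non-negative")
    order = np.argsort(-lam, kind="stable")
    epsilon = np.zeros(lam.size, dtype=int)
    steps = []
    running = 0.0
    for rank0, idx in enumerate(order):
        if rank0 == 0 or running - lam[idx] < 0:
            epsilon[idx] = 1
            running += lam[idx]
        else:
            epsilon[idx] = -1
            running -= lam[idx]
        steps.append((rank0 + 1, int(idx), float(lam[idx]), int(epsilon[idx]), running))
    return PartialSumTrace(
        steps=tuple(steps), epsilon=epsilon, order=order, final_sum=running
    )


def c_m_of(S_n: float, lambda_m: float, record_m: MembershipRecord) -> float:
    """Basis overlap of the rank-1 item that closes the sine-sum constraint.

    c_m = sqrt[((S_n - lambda_m)^2 + interference_m^2) / (mu_A mu_B)].
    """
    product, deviation = _interference_parts(
        record_m.mu_A, record_m.mu_B, record_m.mu_AorB
    )
    value = math.sqrt(((S_n - lambda_m) ** 2 + deviation**2) / product)
    if value > 1.0 + _EDGE_EPS:
        raise InfeasibleModelError(
            f"rank-1 item {record_m.item!r}: required overlap c_m = {value:.6g} > 1; "
            "no unit-norm basis pair realizes it",
            [record_m.item],
        )
    return min(value, 1.0)


def assemble_model(
    table: MembershipTable,
    normalization_tol: float = DEFAULT_NORMALIZATION_TOL,
    check_normalization: bool = True,
) -> DisjunctionModel:
    """Build the full (n+1)-dimensional disjunction model from a table.

    Phase conventions: the A-side phases alpha_k and the basis phases
    gamma_k are set to zero, so each B-side coordinate phase beta_k equals
    the interference phase phi_k.  The rank-1 item m is split over its own
    coordinate and the extra (n+1)-th coordinate with weights b_m*c_m and
    b_m*sqrt(1 - c_m^2); the A vector has zero in the extra coordinate.
    """
    if len(table) == 0:
        raise ValueError("empty membership table")
    if check_normalization and table.normalized:
        residuals, ok = validate_normalization(table, tol=normalization_tol)
        if not ok:
            raise ValueError(
                f"table not normalized within {normalization_tol}: residuals {residuals}"
            )
    zero_items = table.zero_component_items()
    if zero_items:
        raise InfeasibleModelError(
            f"items with mu_A = 0 or mu_B = 0 (phase undefined): {zero_items}",
            zero_items,
        )

    bad: list[str] = []
    lambdas = []
    for rec in table:
        try:
            lambdas.append(lambda_of(rec))
        except InfeasibleModelError:
            bad.append(rec.item)
    if bad:
        raise InfeasibleModelError(
            f"no interference phase exists for items: {bad}", bad
        )
    lambdas = np.array(lambdas)

    trace = rank_and_sign(lambdas)
    m = int(trace.order[0])
    c_m = c_m_of(trace.final_sum, float(lambdas[m]), table.records[m])
    c = np.ones(len(table))
    c[m] = c_m

    rank_of = np.empty(len(table), dtype=int)
    rank_of[trace.order] = np.arange(1, len(table) + 1)

    angles = [
        ItemAngles(
            item=rec.item,
            lambda_k=float(lambdas[k]),
            rank=int(rank_of[k]),
            epsilon=int(trace.epsilon[k]),
            phi_deg=phase_of(rec, c_k=float(c[k]), epsilon_k=int(trace.epsilon[k])),
            c=float(c[k]),
        )
        for k, rec in enumerate(table)
    ]

    n = len(table)
    mu_A, mu_B = table.mu_A, table.mu_B
    a_mod = np.zeros(n + 1)
    a_mod[:n] = np.sqrt(mu_A)
    a_phase = np.zeros(n + 1)

    b_mod = np.zeros(n + 1)
    b_mod[:n] = np.sqrt(mu_B)
    b_mod[m] = math.sqrt(mu_B[m]) * c_m
    b_mod[n] = math.sqrt(mu_B[m]) * math.sqrt(max(0.0, 1.0 - c_m**2))
    b_phase = np.zeros(n + 1)
    b_phase[:n] = [a.phi_deg for a in angles]

    # squared norm inherits the column-sum residual of the input table
    norm_tol = max(1e-9, 2.0 * normalization_tol) if table.normalized else np.inf
    return DisjunctionModel(
        table=table,
        angles=angles,
        trace=trace,
        m_index=m,
        c_m=c_m,
        vector_A=ConceptVector(a_mod, a_phase, norm_tol),
        vector_B=ConceptVector(b_mod, b_phase, norm_tol),
    )


def reconstruct_disjunction(model: DisjunctionModel) -> np.ndarray:
    """Per-item disjunction probabilities implied by the fitted model."""
    return model.reconstruct()


def verify_orthogonality(model: DisjunctionModel) -> OrthogonalityReport:
    """Residuals of the <A|B> = 0 constraint.

    The cosine sum equals the total interference (zero for exactly
    normalized columns); the sine sum is closed by the sign scheme plus the
    c_m tuning.  The overlap magnitude is the hypotenuse of the two.
    """
    mu_A, mu_B = model.table.mu_A, model.table.mu_B
    amp = model.c * np.sqrt(mu_A * mu_B)
    phi = np.radians(model.phi_deg)
    cos_res = float(np.sum(amp * np.cos(phi)))
    sin_res = float(np.sum(amp * np.sin(phi)))
    overlap = abs(np.vdot(model.vector_A.complex, model.vector_B.complex))
    return OrthogonalityReport(cos_res, sin_res, float(overlap))


class ConceptDisjunctionHilbert(BaseEstimator):
    """Scikit-learn style estimator for the two-concept disjunction model.

    Parameters
    ----------
    normalization_tol : float, default 0.003
        Tolerance on |column sum - 1| when validating collapse-probability
        input; covers 4-decimal rounding of printed tables.
    check_normalization : bool, default True
        Validate column normalization before fitting.  Disable for
        membership-weight tables or synthetic disjunction columns whose
        interference does not cancel.

    Attributes
    ----------
    items_ : list of item labels.
    lambda_ : (n,) interference budgets.
    rank_ : (n,) descending-lambda ranks, 1-based.
    epsilon_ : (n,) phase signs in {-1, +1}.
    phi_deg_ : (n,) signed interference phases, degrees.
    c_ : (n,) basis overlaps (all 1 except the rank-1 item).
    c_m_ : overlap of the rank-1 item.
    s_final_ : final greedy partial sum S_n.
    trace_ : :class:`PartialSumTrace` of the sign scheme.
    vector_a_, vector_b_ : fitted :class:`ConceptVector` in C^(n+1).
    model_ : the assembled :class:`DisjunctionModel`.

    Examples
    --------
    >>> from qprototype.datasets import load_fruits_vegetables
    >>> est = ConceptDisjunctionHilbert().fit(load_fruits_vegetables())
    >>> round(est.s_final_, 4)
    0.0154
    """

    def __init__(
        self,
        normalization_tol: float = DEFAULT_NORMALIZATION_TOL,
        check_normalization: bool = True,
    ):
        self.normalization_tol = normalization_tol
        self.check_normalization = check_normalization

    @staticmethod
    def _as_table(X) -> MembershipTable:
        if isinstance(X, MembershipTable):
            return X
        try:
            import pandas as pd

            if isinstance(X, pd.DataFrame):
                return MembershipTable.from_frame(X)
        except ImportError:  # pragma: no cover
            pass
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(
                "X must be a MembershipTable, a DataFrame with columns "
                "item,mu_A,mu_B,mu_AorB, or an (n, 3) array of probabilities"
            )
        records = [
            MembershipRecord(f"item_{k + 1}", *row) for k, row in enumerate(arr)
        ]
        return MembershipTable(records, normalized=False)

    def fit(self, X, y=None) -> "ConceptDisjunctionHilbert":
        """Assemble the Hilbert model from an (n, 3) probability table."""
        table = self._as_table(X)
        model = assemble_model(
            table,
            normalization_tol=self.normalization_tol,
            check_normalization=self.check_normalization,
        )
        self.model_ = model
        self.items_ = table.items
        self.lambda_ = model.lambda_
        self.rank_ = np.array([a.rank for a in model.angles])
        self.epsilon_ = model.epsilon
        self.phi_deg_ = model.phi_deg
        self.c_ = model.c
        self.c_m_ = model.c_m
        self.m_index_ = model.m_index
        self.s_final_ = model.trace.final_sum
        self.trace_ = model.trace
        self.vector_a_ = model.vector_A
        self.vector_b_ = model.vector_B
        self.n_features_in_ = 3
        return self

    def predict(self, X=None) -> np.ndarray:
        """Reconstructed disjunction column of the fitted table.

        ``X`` is accepted for pipeline compatibility; when given, a fresh
        model is assembled for it and its reconstruction returned.
        """
        if X is not None:
            return type(self)(**self.get_params()).fit(X).predict()
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        return self.model_.reconstruct()

    def orthogonality(self) -> OrthogonalityReport:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        return verify_orthogonality(self.model_)

    def score(self, X=None, y=None) -> float:
        """Negative max absolute reconstruction error (higher is better)."""
        if X is not None:
            est = type(self)(**self.get_params()).fit(X)
            return est.score()
        err = np.abs(self.predict() - self.model_.table.mu_AorB)
        return float(-err.max())
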