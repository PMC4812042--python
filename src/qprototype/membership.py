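"""Membership-probability data model and classicality diagnostics.

Concept-combination experiments yield, for each item ``k`` and a pair of
concepts ``A`` and ``B``, three numbers: the collapse (or membership)
probability of the item under ``A``, under ``B``, and under the disjunction
``A or B``.  This module holds those triples, converts raw 7-point Likert
ratings into normalized collapse probabilities, checks column normalization,
and classifies each item against the bounds that any classical (fuzzy-set /
Kolmogorovian) model of the disjunction must respect:

    max(mu_A, mu_B)  <=  mu_AorB  <=  min(1, mu_A + mu_B)

Violations of the lower bound are *underextension* (``double`` when the
disjunction falls below both components); violations of the upper bound are
*overextension*.  These diagnostics are what motivate the interference model
in :mod:`qprototype.hilbert`.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MembershipRecord",
    "MembershipTable",
    "LikertMatrix",
    "Classicality",
    "ClassicalityReport",
    "FormatError",
    "DegenerateInputError",
    "likert_to_collapse",
    "validate_normalization",
    "classify_item",
    "classify_table",
    "prototype_distance",
    "read_membership_table",
    "write_membership_table",
]

#: Default tolerance on |column sum - 1|.  Four-decimal rounding of a
#: 24-item probability column can move its sum by a few units in the
#: fourth decimal.
DEFAULT_NORMALIZATION_TOL = 0.003

REQUIRED_COLUMNS = ("item", "mu_A", "mu_B", "mu_AorB")


class FormatError(ValueError):
    """A delimited input file does not match the expected layout."""


class DegenerateInputError(ValueError):
    """Input admits no meaningful normalization (e.g. all-(-3) ratings)."""


@dataclass(frozen=True)
class MembershipRecord:
    """Collapse/membership probabilities of one item for A, B and 'A or B'."""

    item: str
    mu_A: float
    mu_B: float
    mu_AorB: float

    def __post_init__(self) -> None:
        for name in ("mu_A", "mu_B", "mu_AorB"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1] for item {self.item!r}")

    @property
    def classical_average(self) -> float:
        """(mu_A + mu_B) / 2 — the interference-free disjunction value."""
        return 0.5 * (self.mu_A + self.mu_B)

    @property
    def interference(self) -> float:
        """Deviation of the disjunction from the classical average."""
        return self.mu_AorB - self.classical_average


@dataclass
class MembershipTable:
    """Ordered collection of :class:`MembershipRecord` with unique item labels.

    Parameters
    ----------
    records
        Per-item probability triples, in presentation order.
    normalized
        Whether each of the three probability columns is expected to sum
        to one (collapse-probability semantics).  Membership-weight tables
        (per-item weights, no cross-item constraint) set this to False.
    """

    records: list[MembershipRecord]
    normalized: bool = True
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        labels = [r.item for r in self.records]
        dupes = [x for x, n in Counter(labels).items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate item labels: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def items(self) -> list[str]:
        return [r.item for r in self.records]

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    @property
    def mu_A(self) -> np.ndarray:
        return self.column("mu_A")

    @property
    def mu_B(self) -> np.ndarray:
        return self.column("mu_B")

    @property
    def mu_AorB(self) -> np.ndarray:
        return self.column("mu_AorB")

    def zero_component_items(self) -> list[str]:
        """Items with mu_A == 0 or mu_B == 0.

        The interference phase divides by sqrt(mu_A * mu_B), so these items
        cannot enter the Hilbert construction; they are flagged at load
        time rather than failing deep inside the pipeline.
        """
        return [r.item for r in self.records if r.mu_A == 0.0 or r.mu_B == 0.0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.items,
                "mu_A": self.mu_A,
                "mu_B": self.mu_B,
                "mu_AorB": self.mu_AorB,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, normalized: bool = True) -> "MembershipTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        records = []
        for _, row in frame.iterrows():
            for col in ("mu_A", "mu_B", "mu_AorB"):
                try:
                    float(row[col])
                except (TypeError, ValueError) as exc:
                    raise FormatError(
                        f"non-numeric value {row[col]!r} in column {col}"
                    ) from exc
            records.append(
                MembershipRecord(
                    item=str(row["item"]),
                    mu_A=float(row["mu_A"]),
                    mu_B=float(row["mu_B"]),
                    mu_AorB=float(row["mu_AorB"]),
                )
            )
        extra_cols = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
        extra = frame[extra_cols].reset_index(drop=True) if extra_cols else None
        return cls(records=records, normalized=normalized, extra=extra)


@dataclass
class LikertMatrix:
    """Participants x items matrix of 7-point ratings in {-3..3}.

    Negative values grade non-membership, positive values membership, zero
    marks the borderline.
    """

    ratings: np.ndarray
    items: list[str] | None = None

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings)
        if self.ratings.ndim != 2:
            raise ValueError("ratings must be a 2-D participants x items matrix")
        if not np.issubdtype(self.ratings.dtype, np.integer):
            if not np.all(self.ratings == np.round(self.ratings)):
                raise ValueError("ratings must be integers")
            self.ratings = self.ratings.astype(int)
        if self.ratings.min() < -3 or self.ratings.max() > 3:
            raise ValueError("ratings must lie in {-3,...,3}")
        if self.items is not None and len(self.items) != self.ratings.shape[1]:
            raise ValueError("items header length does not match rating columns")

    @property
    def n_participants(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_items(self) -> int:
        return self.ratings.shape[1]


class Classicality(enum.Enum):
    """Disjunction-semantics classicality label of a probability triple."""

    CLASSICAL = "classical"
    UNDEREXTENSION = "underextension"
    DOUBLE_UNDEREXTENSION = "double-underextension"
    OVEREXTENSION = "overextension"
    # Defined for completeness: a conjunction-side phenomenon (combination
    # weight above both components); unreachable under the disjunction rule
    # implemented by classify_item.
    DOUBLE_OVEREXTENSION = "double-overextension"


@dataclass
class ClassicalityReport:
    """Per-item labels plus counts per label."""

    labels: dict[str, Classicality]

    @property
    def counts(self) -> Counter:
        return Counter(self.labels.values())

    def items_with(self, label: Classicality) -> list[str]:
        return [k for k, v in self.labels.items() if v is label]

    @property
    def n_nonclassical(self) -> int:
        return sum(1 for v in self.labels.values() if v is not Classicality.CLASSICAL)


def likert_to_collapse(
    ratings: LikertMatrix | np.ndarray,
    concept_columns: Sequence[int] | slice | None = None,
) -> np.ndarray:
    """Convert raw 7-point ratings to collapse probabilities over items.

    Ratings are shifted by +3 (making them non-negative), averaged over
    participants per item, and the per-item averages are divided by their
    sum — yielding a probability vector over items that stands in for the
    collapse probabilities a "pick the single best member" experiment
    would produce.

    Parameters
    ----------
    ratings
        Participants x items matrix, entries in {-3..3}.
    concept_columns
        Optional selection of item columns belonging to one concept.

    Returns
    -------
    ndarray
        Non-negative vector summing to 1, one entry per (selected) item.

    Raises
    ------
    DegenerateInputError
        If every shifted rating is zero (all ratings equal -3).
    """
    if not isinstance(ratings, LikertMatrix):
        ratings = LikertMatrix(np.asarray(ratings))
    mat = ratings.ratings
    if concept_columns is not None:
        mat = mat[:, concept_columns]
    shifted = mat + 3.0
    per_item = shifted.mean(axis=0)
    total = per_item.sum()
    if total == 0.0:
        raise DegenerateInputError(
            "all ratings equal -3: shifted sum is zero, no normalization possible"
        )
    return per_item / total


def validate_normalization(
    table: MembershipTable, tol: float = DEFAULT_NORMALIZATION_TOL
) -> tuple[dict[str, float], bool]:
    """Report |column sum - 1| for the three probability columns.

    Returns ``(residuals, ok)`` where ``residuals`` maps column name to the
    absolute deviation of its sum from one and ``ok`` is True when every
    residual is within ``tol``.
    """
    if len(table) == 0:
        raise ValueError("empty membership table")
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    residuals = {
        name: abs(float(table.column(name).sum()) - 1.0)
        for name in ("mu_A", "mu_B", "mu_AorB")
    }
    return residuals, all(r <= tol for r in residuals.values())


def classify_item(record: MembershipRecord) -> Classicality:
    """Classicality label of one triple under disjunction semantics.

    A classical disjunction satisfies
    ``max(mu_A, mu_B) <= mu_AorB <= min(1, mu_A + mu_B)``.
    Falling below the maximum of the components is underextension (below
    *both* components: double underextension); exceeding the additive bound
    is overextension.
    """
    lo, hi = min(record.mu_A, record.mu_B), max(record.mu_A, record.mu_B)
    if record.mu_AorB < lo:
        return Classicality.DOUBLE_UNDEREXTENSION
    if record.mu_AorB < hi:
        return Classicality.UNDEREXTENSION
    if record.mu_AorB > min(1.0, record.mu_A + record.mu_B):
        return Classicality.OVEREXTENSION
    return Classicality.CLASSICAL


def classify_table(table: MembershipTable) -> ClassicalityReport:
    """Classify every record of a table; exactly one label per item."""
    return ClassicalityReport({r.item: classify_item(r) for r in table})


def prototype_distance(
    item_features: Sequence[float], prototype_weights: Sequence[float]
) -> float:
    """Euclidean conceptual distance between an item and a prototype.

    Both arguments are applicability vectors over the same M features; the
    smaller the distance, the more representative the item is of the
    concept.
    """
    x = np.asarray(item_features, dtype=float)
    p = np.asarray(prototype_weights, dtype=float)
    if x.shape != p.shape or x.ndim != 1 or x.size < 1:
        raise ValueError(
            f"feature vectors must be equal-length 1-D with M >= 1, got {x.shape} vs {p.shape}"
        )
    return float(np.sqrt(np.sum((x - p) ** 2)))


def read_membership_table(
    path: str | Path, dialect: str | None = None, normalized: bool = True
) -> MembershipTable:
    """Read a delimited table with header ``item,mu_A,mu_B,mu_AorB``.

    ``dialect`` selects the delimiter (``"csv"`` or ``"tsv"``); by default
    it is sniffed from the header line.  Extra columns are preserved on
    ``table.extra``.
    """
    path = Path(path)
    if dialect is None:
        header = path.read_text().splitlines()[0] if path.exists() else ""
        sep = "\t" if "\t" in header else ","
    else:
        sep = {"csv": ",", "tsv": "\t"}.get(dialect)
        if sep is None:
            raise ValueError(f"unknown dialect {dialect!r}")
    try:
        frame = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return MembershipTable.from_frame(frame, normalized=normalized)


def write_membership_table(
    table: MembershipTable, path: str | Path, dialect: str = "csv"
) -> None:
    """Write a table as delimited text; inverse of :func:`read_membership_table`."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    table.to_frame().to_csv(path, sep=sep, index=False)


def read_likert_matrix(path: str | Path, dialect: str | None = None) -> LikertMatrix:
    """Read a participants x items delimited matrix with an item header row."""
    path = Path(path)
    if dialect is None:
        header = path.read_text().splitlines()[0] if path.exists() else ""
        sep = "\t" if "\t" in header else ","
    else:
        sep = {"csv": ",", "tsv": "\t"}[dialect]
    frame = pd.read_csv(path, sep=sep)
    return LikertMatrix(frame.to_numpy(), items=list(frame.columns))
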