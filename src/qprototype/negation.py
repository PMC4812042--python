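"""Conjunction/negation compatibility statistic and predictions.

For two concepts A, B and their negations A', B', a single classical
probability space forces the four conjunction membership weights to sum to
one, so the statistic

    I = 1 - mu(A and B) - mu(A and B') - mu(A' and B) - mu(A' and B')

vanishes identically (a de Morgan / law-of-total-probability identity).
Measured concept data instead fluctuate around I ~ -0.81, between the
classical value 0 and the pure-quantum value -1.  From three measured
weights the fourth can therefore be predicted two ways: the classical
complement (total 1) or the quantum-informed complement (total 1.81);
their difference is 0.81 for every input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "NegationQuadruple",
    "Prediction",
    "QUANTUM_TOTAL",
    "i_statistic",
    "predict_fourth_classical",
    "predict_fourth_quantum",
]

#: Quantum-informed total of the four conjunction weights, 1 - (-0.81).
QUANTUM_TOTAL = 1.81


@dataclass(frozen=True)
class NegationQuadruple:
    """Membership weights of the four conjunctions of A, B and negations."""

    mu_AB: float
    mu_ABp: float
    mu_ApB: float
    mu_ApBp: float

    def __post_init__(self) -> None:
        for name in ("mu_AB", "mu_ABp", "mu_ApB", "mu_ApBp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")


class Prediction(NamedTuple):
    """A predicted fourth weight plus an out-of-range flag.

    Out-of-range predictions are reported rather than clamped: a quantum
    prediction overflowing [0, 1] is itself diagnostic of how far the
    three measured weights already exceed a classical budget.
    """

    value: float
    in_range: bool


def i_statistic(q: NegationQuadruple) -> float:
    """1 minus the sum of the four conjunction weights.

    Zero for any quadruple drawn from a single classical joint
    distribution; around -0.81 in measured concept data.
    """
    return 1.0 - q.mu_AB - q.mu_ABp - q.mu_ApB - q.mu_ApBp


def _check_three(mu_AB: float, mu_ABp: float, mu_ApB: float) -> None:
    for name, v in (("mu_AB", mu_AB), ("mu_ABp", mu_ABp), ("mu_ApB", mu_ApB)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v!r} outside [0, 1]")


def predict_fourth_classical(mu_AB: float, mu_ABp: float, mu_ApB: float) -> Prediction:
    """Classical complement: mu(A' and B') = 1 - (sum of the other three)."""
    _check_three(mu_AB, mu_ABp, mu_ApB)
    value = 1.0 - mu_AB - mu_ABp - mu_ApB
    return Prediction(value, 0.0 <= value <= 1.0)


def predict_fourth_quantum(
    mu_AB: float, mu_ABp: float, mu_ApB: float, quantum_total: float = QUANTUM_TOTAL
) -> Prediction:
    """Quantum-informed complement: total ``quantum_total`` instead of 1.

    The default total 1.81 makes the quantum prediction exceed the
    classical one by 0.81 for every input.
    """
    _check_three(mu_AB, mu_ABp, mu_ApB)
    value = quantum_total - mu_AB - mu_ABp - mu_ApB
    return Prediction(value, 0.0 <= value <= 1.0)
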