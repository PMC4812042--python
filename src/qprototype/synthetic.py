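"""Seeded synthetic-data generators for every pipeline input.

Two regimes are provided.  The *quantum* regime draws normalized collapse
probabilities for two concepts, draws a known interference phase per item,
and builds the disjunction column through the interference formula — so the
ground-truth phases are recorded and parameter recovery can be tested
end-to-end.  The *classical* regime draws a latent 2x2 joint distribution
per item and derives all combination weights from it, producing data that
every classicality diagnostic must pass and on which the conjunction/
negation statistic vanishes identically.  A Likert sampler emulates the
7-point rating experiment whose shift-and-normalize conversion converges to
prescribed collapse probabilities.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .membership import LikertMatrix, MembershipRecord, MembershipTable
from .negation import NegationQuadruple

__all__ = [
    "GeneratorConfig",
    "QuantumSample",
    "ClassicalSample",
    "gen_quantum_table",
    "gen_classical_table",
    "gen_likert",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic generators.

    Parameters
    ----------
    n_items : number of items (>= 2); 24 matches the reference study.
    seed : RNG seed; same seed, same output.
    regime : "quantum" (interference-built disjunction) or "classical"
        (latent 2x2 joint per item).
    phase_low_deg, phase_high_deg : support of the |phase| distribution in
        the quantum regime.  The default [30, 150] keeps cos(phi) away from
        +/-1, where the arccos recovery is ill-conditioned.
    random_signs : draw the phase sign uniformly from {-1, +1}.
    participants : participant count for the Likert simulation.
    concentration : symmetric Dirichlet concentration for the collapse
        probability columns; 5 gives the moderate spread (roughly a
        tenfold max/min ratio at n = 24) seen in real membership studies.
    rescale_disjunction : if True, rescale the generated disjunction
        column to sum to one (destroying the exact interference identity);
        default leaves it exact and reports the sum.
    """

    n_items: int = 24
    seed: int = 0
    regime: str = "quantum"
    phase_low_deg: float = 30.0
    phase_high_deg: float = 150.0
    random_signs: bool = True
    participants: int = 100
    concentration: float = 5.0
    rescale_disjunction: bool = False
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise ValueError("n_items must be >= 2")
        if self.regime not in ("quantum", "classical"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass(frozen=True)
class QuantumSample:
    """A generated table plus its ground-truth phases."""

    table: MembershipTable
    phases_deg: np.ndarray
    disjunction_sum: float


@dataclass(frozen=True)
class ClassicalSample:
    """A generated membership-weight table plus the latent joint cells."""

    table: MembershipTable
    quadruples: tuple[NegationQuadruple, ...]


def _labels(n: int) -> list[str]:
    return [f"item_{k + 1}" for k in range(n)]


def gen_quantum_table(config: GeneratorConfig) -> QuantumSample:
    """Generate a table whose disjunction column is built by interference.

    mu_AorB = (mu_A + mu_B)/2 + sqrt(mu_A mu_B) cos(phi) with known phi
    per item (unit basis overlap).  By the AM-GM inequality the result
    always lies in [0, 1]; a bounded resampling loop guards degenerate
    draws.  The A and B columns are Dirichlet-normalized (sum to one); the
    disjunction column is left exact and its sum reported.
    """
    if config.regime != "quantum":
        raise ValueError("config.regime must be 'quantum'")
    rng = np.random.default_rng(config.seed)
    n = config.n_items
    alpha = np.full(n, config.concentration)
    for _ in range(config.max_retries):
        mu_A = rng.dirichlet(alpha)
        mu_B = rng.dirichlet(alpha)
        mag = rng.uniform(config.phase_low_deg, config.phase_high_deg, size=n)
        signs = rng.choice([-1.0, 1.0], size=n) if config.random_signs else np.ones(n)
        phi = signs * mag
        mu_D = 0.5 * (mu_A + mu_B) + np.sqrt(mu_A * mu_B) * np.cos(np.radians(phi))
        if np.all((mu_D >= 0.0) & (mu_D <= 1.0)) and np.all(mu_A * mu_B > 0):
            break
    else:  # pragma: no cover - unreachable for sane configs
        raise RuntimeError("could not generate an admissible table")
    if config.rescale_disjunction:
        mu_D = mu_D / mu_D.sum()
    records = [
        MembershipRecord(lab, float(a), float(b), float(d))
        for lab, a, b, d in zip(_labels(n), mu_A, mu_B, mu_D)
    ]
    return QuantumSample(
        table=MembershipTable(records, normalized=config.rescale_disjunction),
        phases_deg=phi,
        disjunction_sum=float(mu_D.sum()),
    )


def gen_classical_table(config: GeneratorConfig) -> ClassicalSample:
    """Generate per-item weights from latent classical joint distributions.

    Each item gets a 2x2 joint (cells for A&B, A&B', A'&B, A'&B') drawn
    from a flat Dirichlet; marginals give mu_A and mu_B, and the
    disjunction weight is mu_A + mu_B - mu(A and B).  The columns are
    per-item membership weights (no cross-item normalization), so the
    table carries ``normalized=False``.
    """
    if config.regime != "classical":
        raise ValueError("config.regime must be 'classical'")
    rng = np.random.default_rng(config.seed)
    n = config.n_items
    cells = rng.dirichlet(np.ones(4), size=n)  # columns: p11, p10, p01, p00
    records = []
    quads = []
    for lab, (p11, p10, p01, p00) in zip(_labels(n), cells):
        mu_A = p11 + p10
        mu_B = p11 + p01
        mu_D = mu_A + mu_B - p11
        records.append(MembershipRecord(lab, float(mu_A), float(mu_B), float(mu_D)))
        quads.append(
            NegationQuadruple(float(p11), float(p10), float(p01), float(p00))
        )
    return ClassicalSample(
        table=MembershipTable(records, normalized=False), quadruples=tuple(quads)
    )


def gen_likert(
    true_weights: Sequence[float], participants: int, seed: int = 0
) -> LikertMatrix:
    """Sample 7-point ratings whose conversion targets given probabilities.

    For each participant x item, the shifted rating (0..6) is a
    binomial(6, w_i) draw, so its mean is 6*w_i; shift-and-normalize of
    the sample therefore converges to ``true_weights`` as the participant
    count grows.
    """
    w = np.asarray(true_weights, dtype=float)
    if w.ndim != 1 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("true_weights must be a probability vector")
    if np.any(w > 1.0):
        raise ValueError("weights must lie in [0, 1]")
    if participants < 1:
        raise ValueError("participants must be >= 1")
    rng = np.random.default_rng(seed)
    shifted = rng.binomial(6, np.broadcast_to(w, (participants, w.size)))
    return LikertMatrix(shifted - 3, items=_labels(w.size))
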