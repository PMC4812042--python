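"""Packaged reference datasets.

The toolkit ships the published 24-item Fruits/Vegetables membership study
(collapse probabilities for *Fruits*, *Vegetables* and *Fruits or
Vegetables*, together with the published interference parameters) and the
corresponding two-dimensional wave-field solution (item coordinates,
phase-polynomial coefficients and Gaussian packet parameters).  Both load
from plain CSV files bundled with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .membership import MembershipTable

__all__ = [
    "load_fruits_vegetables",
    "load_wavefield_solution",
    "WavefieldSolution",
]

#: Monomial basis of the phase polynomial, in the fixed published order.
MONOMIAL_BASIS: tuple[tuple[int, int], ...] = (
    (0, 0),
    (1, 0), (0, 1),
    (2, 0), (1, 1), (0, 2),
    (3, 0), (2, 1), (1, 2), (0, 3),
    (4, 0), (3, 1), (2, 2), (1, 3), (0, 4),
    (5, 0), (4, 1), (3, 2), (2, 3), (1, 4), (0, 5),
    (6, 0), (5, 1), (4, 2),
)


def _read_packaged_csv(name: str) -> pd.DataFrame:
    ref = resources.files("qprototype.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_fruits_vegetables() -> MembershipTable:
    """The 24-item Fruits/Vegetables collapse-probability table.

    The returned table carries the three probability columns as records;
    the published interference columns (``lambda_pub``, ``lambda_rank_pub``,
    ``epsilon_pub``, ``phi_deg_pub``) are preserved on ``table.extra`` for
    regression comparisons.
    """
    frame = _read_packaged_csv("table1_fruits_vegetables.csv")
    return MembershipTable.from_frame(frame, normalized=True)


@dataclass(frozen=True)
class WavefieldSolution:
    """Published wave-field illustration parameters.

    Attributes
    ----------
    items : list of item labels, in table order.
    coordinates : (24, 2) array of item locations in the plane.
    monomials : names of the 24 polynomial basis terms, in solve order.
    coefficients : published phase-polynomial coefficients (degrees).
    gaussian : mapping of Gaussian packet parameters
        (D_A, sigma_Ax, sigma_Ay, D_B, sigma_Bx, sigma_By, a, b).
    """

    items: tuple[str, ...]
    coordinates: np.ndarray
    monomials: tuple[str, ...]
    coefficients: np.ndarray
    gaussian: dict[str, float]


def load_wavefield_solution() -> WavefieldSolution:
    """Item coordinates, published F coefficients and Gaussian parameters."""
    frame = _read_packaged_csv("table2_wavefield_solution.csv")
    gauss = _read_packaged_csv("table2_gaussian_parameters.csv")
    return WavefieldSolution(
        items=tuple(frame["item"]),
        coordinates=frame[["x", "y"]].to_numpy(dtype=float),
        monomials=tuple(frame["monomial"]),
        coefficients=frame["F"].to_numpy(dtype=float),
        gaussian=dict(zip(gauss["parameter"], gauss["value"].astype(float))),
    )
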