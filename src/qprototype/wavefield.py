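"""Two-dimensional interfering-prototype wave field.

The disjunction of two concepts can be illustrated as the interference of
two Gaussian wave packets in a plane: one packet per concept, each item
placed at a location where the packet densities (times a small effective
cell weight delta_eff) reproduce its collapse probabilities, and a smooth
phase-difference field theta(x, y) interpolating the per-item interference
phases.  The combined density

    |psi_AorB|^2 = (|psi_A|^2 + |psi_B|^2)/2 + |psi_A psi_B| cos(theta)

then reproduces the disjunction probabilities at the item locations and
draws the familiar fringe pattern in between.

The phase field is a polynomial in x and y over a fixed basis of 24
monomials; solving the 24x24 interpolation system at the item coordinates
is handled by :class:`PhaseFieldInterpolator` (scikit-learn style fit /
predict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .datasets import MONOMIAL_BASIS, load_wavefield_solution
from .membership import MembershipRecord, MembershipTable

__all__ = [
    "GaussianPacket",
    "GaussianPair",
    "PhaseField",
    "PhaseFieldInterpolator",
    "WaveGrid",
    "LocationError",
    "packet_density",
    "locate_item",
    "theta_targets",
    "design_matrix",
    "solve_phase_field",
    "interference_density",
    "density_at_points",
    "oneD_wave_figure",
    "render_grid",
]

#: Default grid: covers all published item coordinates with margin.
DEFAULT_EXTENT = (-12.0, 16.0, -4.0, 12.0)
DEFAULT_SHAPE = (600, 400)  # (nx, ny)


class LocationError(ValueError):
    """No admissible location exists for an item on the two packets."""


@dataclass(frozen=True)
class GaussianPacket:
    """2-D Gaussian probability-density packet.

    ``amplitude`` is the peak *density* (the squared-modulus height), so
    the density at (x, y) is
    D * exp(-((x-x0)^2/(2 sx^2) + (y-y0)^2/(2 sy^2))).
    """

    amplitude: float
    sigma_x: float
    sigma_y: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("amplitude and widths must be positive")

    def density(self, x, y) -> np.ndarray:
        x0, y0 = self.center
        return self.amplitude * np.exp(
            -(
                (np.asarray(x, dtype=float) - x0) ** 2 / (2 * self.sigma_x**2)
                + (np.asarray(y, dtype=float) - y0) ** 2 / (2 * self.sigma_y**2)
            )
        )


@dataclass(frozen=True)
class GaussianPair:
    """The two concept packets plus the effective cell weight delta_eff.

    delta_eff approximates the integral of a density over an item's small
    cell by (cell area) x (density at the cell center); it calibrates
    densities to probabilities via mu = delta_eff * |psi|^2.
    """

    packet_A: GaussianPacket
    packet_B: GaussianPacket
    delta_eff: float = 0.1

    def __post_init__(self) -> None:
        if self.delta_eff <= 0:
            raise ValueError("delta_eff must be positive")

    @classmethod
    def published(cls) -> "GaussianPair":
        """The published Fruits/Vegetables packet parameters (delta_eff 0.1)."""
        g = load_wavefield_solution().gaussian
        return cls(
            packet_A=GaussianPacket(g["D_A"], g["sigma_Ax"], g["sigma_Ay"], (0.0, 0.0)),
            packet_B=GaussianPacket(
                g["D_B"], g["sigma_Bx"], g["sigma_By"], (g["a"], g["b"])
            ),
            delta_eff=0.1,
        )

    @classmethod
    def calibrated(
        cls,
        mu_A_peak: float,
        mu_B_peak: float,
        sigmas_A: tuple[float, float],
        sigmas_B: tuple[float, float],
        center_B: tuple[float, float],
        delta_eff: float = 0.1,
    ) -> "GaussianPair":
        """Set peak densities so delta_eff * D equals the peak-item probability.

        The packet-A peak sits at the most probable A item (placed at the
        origin) and the packet-B peak at the most probable B item.
        """
        return cls(
            packet_A=GaussianPacket(mu_A_peak / delta_eff, *sigmas_A, (0.0, 0.0)),
            packet_B=GaussianPacket(mu_B_peak / delta_eff, *sigmas_B, center_B),
            delta_eff=delta_eff,
        )


def packet_density(packet: GaussianPacket, point: tuple[float, float]) -> float:
    """Density of one packet at a point."""
    return float(packet.density(point[0], point[1]))


def _ellipse_radius(packet: GaussianPacket, mu: float, delta_eff: float) -> float:
    """Squared-radius parameter R with delta*density = mu on the level set
    (x-x0)^2/(2 sx^2) + (y-y0)^2/(2 sy^2) = R."""
    peak = delta_eff * packet.amplitude
    if mu > peak * (1 + 1e-12):
        raise LocationError(
            f"required probability {mu} exceeds peak delta*density {peak}"
        )
    return max(0.0, math.log(peak / mu))


def locate_item(
    record: MembershipRecord,
    pair: GaussianPair,
    branch_hint: tuple[float, float] | None = None,
    atol: float = 5e-4,
):
    """Locations where both packet densities reproduce the item's probabilities.

    Solves delta_eff*|psi_A|^2 = mu_A and delta_eff*|psi_B|^2 = mu_B — the
    intersection of two axis-aligned ellipses.  The A-ellipse is
    parametrized by angle and the B-constraint residual root-found along
    it; up to four intersections exist.

    Returns the intersection nearest ``branch_hint`` when a hint is given,
    the unique intersection when there is only one, and the full list
    otherwise.  Raises :class:`LocationError` when no real intersection
    exists (probability above a peak, or disjoint ellipses).
    """
    R_A = _ellipse_radius(pair.packet_A, record.mu_A, pair.delta_eff)
    R_B = _ellipse_radius(pair.packet_B, record.mu_B, pair.delta_eff)
    ax, ay = pair.packet_A.center
    bx, by = pair.packet_B.center
    sA = (pair.packet_A.sigma_x, pair.packet_A.sigma_y)
    sB = (pair.packet_B.sigma_x, pair.packet_B.sigma_y)

    def b_residual_at(x, y):
        return (x - bx) ** 2 / (2 * sB[0] ** 2) + (y - by) ** 2 / (2 * sB[1] ** 2) - R_B

    # A probability at (or within atol of) the packet peak collapses the
    # ellipse to the center point; the other constraint is then only checked.
    if pair.delta_eff * pair.packet_A.amplitude - record.mu_A <= atol:
        mu_B_there = pair.delta_eff * pair.packet_B.density(ax, ay)
        if abs(mu_B_there - record.mu_B) > atol:
            raise LocationError(
                f"item {record.item!r}: A-constraint forces {(ax, ay)} but the "
                f"B-density there gives {mu_B_there:.6g} != {record.mu_B}"
            )
        return (ax, ay)
    if pair.delta_eff * pair.packet_B.amplitude - record.mu_B <= atol:
        mu_A_there = pair.delta_eff * pair.packet_A.density(bx, by)
        if abs(mu_A_there - record.mu_A) > atol:
            raise LocationError(
                f"item {record.item!r}: B-constraint forces {(bx, by)} but the "
                f"A-density there gives {mu_A_there:.6g} != {record.mu_A}"
            )
        return (bx, by)

    rA = math.sqrt(2 * R_A)

    def g(t):
        x = ax + rA * sA[0] * math.cos(t)
        y = ay + rA * sA[1] * math.sin(t)
        return b_residual_at(x, y)

    ts = np.linspace(0.0, 2 * math.pi, 1441)
    vals = np.array([g(t) for t in ts])
    roots = []
    for i in range(len(ts) - 1):
        if vals[i] == 0.0:
            roots.append(ts[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, ts[i], ts[i + 1], xtol=1e-14))
    if not roots and R_B == 0.0:
        # degenerate B-ellipse: check whether the B center lies on the A-ellipse
        if abs(pair.delta_eff * pair.packet_A.density(bx, by) - record.mu_A) <= atol:
            return (bx, by)
    if not roots:
        raise LocationError(
            f"item {record.item!r}: the two probability ellipses do not intersect"
        )
    points = []
    for t in roots:
        p = (ax + rA * sA[0] * math.cos(t), ay + rA * sA[1] * math.sin(t))
        if not any(math.hypot(p[0] - q[0], p[1] - q[1]) < 1e-8 for q in points):
            points.append(p)
    if branch_hint is not None:
        return min(
            points, key=lambda p: math.hypot(p[0] - branch_hint[0], p[1] - branch_hint[1])
        )
    if len(points) == 1:
        return points[0]
    return points


def theta_targets(table: MembershipTable, signs: Sequence[int]) -> np.ndarray:
    """Signed per-item phase targets (degrees) at unit basis overlap.

    theta_k = epsilon_k * arccos[(mu_AorB - (mu_A+mu_B)/2) / sqrt(mu_A mu_B)],
    with c = 1 for every item including the rank-1 item (the wave-field
    illustration does not split any basis direction).
    """
    signs = np.asarray(signs, dtype=float)
    if signs.shape != (len(table),):
        raise ValueError("signs must provide one entry per item")
    mu_A, mu_B = table.mu_A, table.mu_B
    dev = table.mu_AorB - 0.5 * (mu_A + mu_B)
    arg = dev / np.sqrt(mu_A * mu_B)
    if np.any(np.abs(arg) > 1 + 1e-12):
        bad = [table.items[i] for i in np.flatnonzero(np.abs(arg) > 1 + 1e-12)]
        raise ValueError(f"arccos domain violated for items: {bad}")
    return signs * np.degrees(np.arccos(np.clip(arg, -1.0, 1.0)))


def design_matrix(coords: np.ndarray) -> np.ndarray:
    """Monomial design matrix over the fixed 24-term basis.

    Basis order: 1, x, y, x^2, xy, y^2, ..., y^5, x^6, x^5 y, x^4 y^2.
    """
    coords = np.asarray(coords, dtype=float)
    x, y = coords[:, 0], coords[:, 1]
    return np.column_stack([x**i * y**j for i, j in MONOMIAL_BASIS])


@dataclass(frozen=True)
class PhaseField:
    """Phase-difference polynomial theta(x, y), coefficients in degrees."""

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.coefficients).shape != (len(MONOMIAL_BASIS),):
            raise ValueError(
                f"phase field needs exactly {len(MONOMIAL_BASIS)} coefficients"
            )

    def evaluate(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for coef, (i, j) in zip(self.coefficients, MONOMIAL_BASIS):
            out += coef * x**i * y**j
        return out


class PhaseFieldInterpolator(BaseEstimator):
    """Exact polynomial interpolator of per-item phases over the plane.

    Fits the 24 monomial coefficients F so that theta(x_k, y_k) equals the
    target phase of every item: a square linear solve on the monomial
    design matrix.  ``predict`` evaluates theta (degrees) at new points.

    Parameters
    ----------
    max_condition : float, default 1e13
        Condition-number bound above which the design matrix is reported
        as numerically singular.  The published item coordinates give a
        condition around 1e9, harmless at the achieved interpolation
        residuals (< 1e-8 degrees).
    """

    def __init__(self, max_condition: float = 1e13):
        self.max_condition = max_condition

    def fit(self, X, y) -> "PhaseFieldInterpolator":
        coords = np.asarray(X, dtype=float)
        targets = np.asarray(y, dtype=float)
        n = len(MONOMIAL_BASIS)
        if coords.shape != (n, 2) or targets.shape != (n,):
            raise ValueError(
                f"need exactly {n} (x, y) coordinates and {n} phase targets"
            )
        if len(np.unique(coords, axis=0)) != n:
            raise ValueError("item coordinates must be pairwise distinct")
        P = design_matrix(coords)
        cond = np.linalg.cond(P)
        if not np.isfinite(cond) or cond > self.max_condition:
            raise np.linalg.LinAlgError(
                f"phase-field design matrix is ill-conditioned (cond ~ {cond:.3g})"
            )
        self.coefficients_ = np.linalg.solve(P, targets)
        self.condition_ = float(cond)
        self.field_ = PhaseField(self.coefficients_)
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "field_"):
            raise AttributeError("interpolator is not fitted")
        pts = np.asarray(X, dtype=float)
        return self.field_.evaluate(pts[..., 0], pts[..., 1])


def solve_phase_field(coords: np.ndarray, targets_deg: Sequence[float]) -> PhaseField:
    """One-shot solve of the 24x24 phase interpolation system."""
    return PhaseFieldInterpolator().fit(coords, targets_deg).field_


@dataclass
class WaveGrid:
    """Sampled density layer on a rectangular grid."""

    x: np.ndarray          # (nx,)
    y: np.ndarray          # (ny,)
    density: np.ndarray    # (ny, nx)
    layer: str             # "A", "B" or "A-or-B"
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT


def _grid_axes(extent, shape):
    x0, x1, y0, y1 = extent
    nx, ny = shape
    return np.linspace(x0, x1, nx), np.linspace(y0, y1, ny)


def interference_density(
    pair: GaussianPair,
    phase_field: PhaseField | None,
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    layer: str = "A-or-B",
) -> WaveGrid:
    """Sampled density of one layer over a rectangular grid.

    Layer "A-or-B" is the superposition density
    (d_A + d_B)/2 + sqrt(d_A d_B) cos(theta); with ``phase_field`` None the
    interference term is dropped (plain average of the single-concept
    layers).
    """
    xs, ys = _grid_axes(extent, shape)
    X, Y = np.meshgrid(xs, ys)
    dA = pair.packet_A.density(X, Y)
    dB = pair.packet_B.density(X, Y)
    if layer == "A":
        dens = dA
    elif layer == "B":
        dens = dB
    elif layer == "A-or-B":
        dens = 0.5 * (dA + dB)
        if phase_field is not None:
            dens = dens + np.sqrt(dA * dB) * np.cos(
                np.radians(phase_field.evaluate(X, Y))
            )
    else:
        raise ValueError(f"unknown layer {layer!r}")
    return WaveGrid(x=xs, y=ys, density=dens, layer=layer, extent=extent)


def density_at_points(
    pair: GaussianPair, phase_field: PhaseField, points: np.ndarray
) -> np.ndarray:
    """Superposition density at arbitrary points (no grid)."""
    pts = np.asarray(points, dtype=float)
    dA = pair.packet_A.density(pts[..., 0], pts[..., 1])
    dB = pair.packet_B.density(pts[..., 0], pts[..., 1])
    theta = phase_field.evaluate(pts[..., 0], pts[..., 1])
    return 0.5 * (dA + dB) + np.sqrt(dA * dB) * np.cos(np.radians(theta))


def oneD_wave_figure(
    record: MembershipRecord,
    phi_deg: float,
    x_range: tuple[float, float] = (-2 * math.pi, 2 * math.pi),
    n_samples: int = 500,
) -> dict[str, np.ndarray]:
    """One-dimensional cosine-wave picture of a single item's interference.

    Returns sampled curves sqrt(mu_A) cos(x), sqrt(mu_B) cos(x + phi) and
    their half-sum; the half-sum amplitude at the origin is the amplitude
    of the item in the disjunction.
    """
    x = np.linspace(x_range[0], x_range[1], n_samples)
    wave_A = math.sqrt(record.mu_A) * np.cos(x)
    wave_B = math.sqrt(record.mu_B) * np.cos(x + math.radians(phi_deg))
    return {
        "x": x,
        "wave_A": wave_A,
        "wave_B": wave_B,
        "half_sum": 0.5 * (wave_A + wave_B),
    }


def render_grid(
    grid: WaveGrid,
    coords: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
    path=None,
    cmap: str = "inferno",
):
    """Render a density layer to a raster image with item markers.

    Deterministic given its inputs; returns the matplotlib figure (and
    writes PNG when ``path`` is given).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.imshow(
        grid.density,
        origin="lower",
        extent=grid.extent,
        cmap=cmap,
        aspect="equal",
        interpolation="bilinear",
    )
    if coords is not None:
        coords = np.asarray(coords, dtype=float)
        ax.plot(coords[:, 0], coords[:, 1], "o", ms=3, color="white", mec="black")
        if labels is not None:
            for (cx, cy), lab in zip(coords, labels):
                ax.annotate(
                    str(lab), (cx, cy), fontsize=5, color="white",
                    xytext=(2, 2), textcoords="offset points",
                )
    ax.set_title(f"layer {grid.layer}")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
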