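"""Contact angles of sessile cylindrical droplets from 2-D density fields.

Simulated droplets that are periodic along one box axis have a circular-cap
cross-section, so the contact angle follows from geometry once the
liquid-vapor interface is located in the time-averaged density map:

1. the interface is the iso-density contour at a fraction (default half)
   of the bulk liquid density, located with sub-bin precision by marching
   squares;
2. a circle is fitted to the interface points, skipping a thin exclusion
   zone above the substrate where density layering distorts the contour;
3. the contact angle at the substrate plane z = z0 is
   cos(theta) = (z0 - zc)/R from the fitted center height zc and radius R;
4. angles from droplets of several sizes are extrapolated to the
   macroscopic limit by ordinary least squares of cos(theta) against 1/R
   (cylindrical caps carry no line tension; 1/R absorbs the residual
   finite-size bias).

Coordinates: ``grid[i, j]`` is the density at z = z_min + i*dz (rows,
ascending) and y = y_min + j*dy (columns).  All lengths in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from .errors import (
    DegenerateFitError,
    DetachedDropletError,
    DomainError,
    NoInterfaceError,
)

__all__ = [
    "DensityField",
    "CircleFit",
    "AngleEstimate",
    "ExtrapolationResult",
    "extract_interface",
    "fit_circle",
    "contact_angle_from_fit",
    "extrapolate_macroscopic",
    "analyze_droplet",
]

#: Default height above the substrate plane excluded from the circle fit, nm.
DEFAULT_Z_EXCL = 0.8


@dataclass(frozen=True)
class DensityField:
    """Time-averaged 2-D solvent density map of a cylindrical droplet."""

    grid: np.ndarray  # density, rows = z ascending, cols = y
    dy: float  # bin width along y, nm
    dz: float  # bin width along z, nm
    z0: float  # substrate-plane height, nm
    rho_bulk: float  # bulk liquid density, same unit as grid
    y_min: float = 0.0
    z_min: float = 0.0

    def __post_init__(self) -> None:
        if self.dy <= 0 or self.dz <= 0:
            raise DomainError("bin widths dy, dz must be positive")
        if self.rho_bulk <= 0:
            raise DomainError("rho_bulk must be positive")
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2:
            raise DomainError("grid must be a 2-D array")
        if np.any(grid < 0):
            raise DomainError("grid densities must be non-negative")
        object.__setattr__(self, "grid", grid)


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle through interface points (nm)."""

    yc: float
    zc: float
    R: float
    rms_residual: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise DegenerateFitError(f"non-positive fitted radius {self.R!r}")


@dataclass(frozen=True)
class AngleEstimate:
    """A (droplet radius, contact angle) measurement for one droplet."""

    theta: float  # degrees, through the liquid
    R: float  # nm
    n_points: int
    cos_theta: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cos_theta", math.cos(math.radians(self.theta))
        )


@dataclass(frozen=True)
class ExtrapolationResult:
    """Macroscopic contact angle from a 1/R extrapolation."""

    theta: float  # degrees, infinite-droplet limit
    slope: float  # d cos(theta) / d(1/R), nm
    intercept: float  # cos(theta) at 1/R = 0
    n: int


def extract_interface(field: DensityField, iso_fraction: float = 0.5) -> np.ndarray:
    """Locate the liquid-vapor interface as iso-density contour points.

    Runs marching squares at the level ``iso_fraction * rho_bulk`` and
    returns an (N, 2) array of (y, z) points in nm, interpolated linearly
    along grid edges (sub-bin resolution).  Points on the grid border or at
    or below the substrate plane are dropped so that only the free
    liquid-vapor boundary remains.
    """
    if not 0.0 < iso_fraction < 1.0:
        raise DomainError(f"iso_fraction={iso_fraction!r} outside (0, 1)")
    level = iso_fraction * field.rho_bulk
    grid = field.grid
    if grid.min() >= level or grid.max() <= level:
        raise NoInterfaceError(
            f"density grid does not cross the iso-level {level:.4g}"
        )
    contours = measure.find_contours(grid, level)
    if not contours:
        raise NoInterfaceError("no iso-density contour found")
    nz, ny = grid.shape
    pts = []
    eps = 1e-9
    for contour in contours:
        rows, cols = contour[:, 0], contour[:, 1]
        interior = (
            (rows > eps) & (rows < nz - 1 - eps)
            & (cols > eps) & (cols < ny - 1 - eps)
        )
        z = field.z_min + rows[interior] * field.dz
        y = field.y_min + cols[interior] * field.dy
        above = z > field.z0 + eps
        pts.append(np.column_stack([y[above], z[above]]))
    points = np.concatenate(pts) if pts else np.empty((0, 2))
    if points.shape[0] == 0:
        raise NoInterfaceError("no interface points above the substrate plane")
    return points


def _kasa_circle(y: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) circle fit: linear least squares on y^2 + z^2."""
    A = np.column_stack([2.0 * y, 2.0 * z, np.ones_like(y)])
    b = y * y + z * z
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateFitError("points are collinear or otherwise degenerate")
    yc, zc, c = sol
    r2 = c + yc * yc + zc * zc
    if r2 <= 0:
        raise DegenerateFitError("degenerate circle fit (non-positive radius)")
    return float(yc), float(zc), float(math.sqrt(r2))


def fit_circle(
    points: np.ndarray,
    z0: float,
    z_excl: float = DEFAULT_Z_EXCL,
    refine: bool = True,
) -> CircleFit:
    """Fit a circle to interface points above the near-substrate zone.

    Points with z <= z0 + z_excl are excluded: density layering near the
    wall bends the contour away from the macroscopic circular cap.  The
    algebraic least-squares (Kasa) solution is optionally polished by a
    geometric (orthogonal-distance) Gauss-Newton refinement.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise DomainError("points must be an (N, 2) array of (y, z)")
    keep = points[:, 1] > z0 + z_excl
    y, z = points[keep, 0], points[keep, 1]
    if y.size < 5:
        raise DegenerateFitError(
            f"only {y.size} usable points above z0 + z_excl (need >= 5)"
        )
    yc, zc, R = _kasa_circle(y, z)
    if refine:
        from scipy.optimize import least_squares

        def resid(p):
            return np.hypot(y - p[0], z - p[1]) - p[2]

        sol = least_squares(resid, x0=[yc, zc, R], method="lm")
        yc, zc, R = map(float, sol.x)
        if R <= 0:
            raise DegenerateFitError("geometric refinement collapsed the circle")
    rms = float(np.sqrt(np.mean((np.hypot(y - yc, z - zc) - R) ** 2)))
    return CircleFit(yc=yc, zc=zc, R=R, rms_residual=rms, n_points=int(y.size))


def contact_angle_from_fit(fit: CircleFit, z0: float) -> AngleEstimate:
    """Contact angle where the fitted circle meets the substrate plane.

    Measured through the liquid: cos(theta) = (z0 - zc)/R, so a center on
    the plane gives 90 deg and a center above it an obtuse (hydrophobic)
    angle.
    """
    cos_theta = (z0 - fit.zc) / fit.R
    if abs(cos_theta) > 1.0:
        raise DetachedDropletError(
            f"fitted circle (zc={fit.zc:.3f}, R={fit.R:.3f}) does not "
            f"intersect the substrate plane z0={z0:.3f}"
        )
    theta = math.degrees(math.acos(cos_theta))
    return AngleEstimate(theta=theta, R=fit.R, n_points=fit.n_points)


def extrapolate_macroscopic(
    estimates: Sequence[AngleEstimate],
) -> ExtrapolationResult:
    """Macroscopic contact angle from droplets of several sizes.

    Ordinary least squares of cos(theta) against curvature 1/R; the
    intercept is cos(theta) of an infinitely large droplet.
    """
    if len(estimates) < 2:
        raise DomainError("need at least 2 angle estimates to extrapolate")
    R = np.array([e.R for e in estimates], dtype=float)
    if np.unique(R).size < 2:
        raise DomainError("need at least 2 distinct droplet radii")
    cos_t = np.array([e.cos_theta for e in estimates], dtype=float)
    slope, intercept = np.polyfit(1.0 / R, cos_t, 1)
    if abs(intercept) > 1.0:
        raise DomainError(
            f"extrapolated cos(theta) = {intercept:.4f} outside [-1, 1]; "
            f"slope {slope:.4f} nm over R in [{R.min():.3g}, {R.max():.3g}] nm"
        )
    return ExtrapolationResult(
        theta=math.degrees(math.acos(intercept)),
        slope=float(slope),
        intercept=float(intercept),
        n=len(estimates),
    )


def analyze_droplet(
    field: DensityField,
    iso_fraction: float = 0.5,
    z_excl: float = DEFAULT_Z_EXCL,
    refine: bool = True,
) -> AngleEstimate:
    """Full pipeline: interface extraction, circle fit, contact angle."""
    points = extract_interface(field, iso_fraction)
    fit = fit_circle(points, field.z0, z_excl=z_excl, refine=refine)
    return contact_angle_from_fit(fit, field.z0)
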