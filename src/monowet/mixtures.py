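"""Solvent-exchange thermodynamics for binary water/organic mixtures.

When a short-chain alcohol is mixed into water, the liquid-vapor surface
tension gamma drops from gamma_w (72 mN/m) toward gamma_alc (22 mN/m for
ethanol) while the contact angle on a given solid falls at the same time.
The two effects partly cancel in the adhesion tension gamma*cos(theta).
Following the revised Zisman picture (cos theta linear in 1/gamma on a
fixed solid), the adhesion tension is modeled as a straight line in gamma,

    gamma*cos(theta) = c0 + c1*gamma,

anchored by two reference states: neat water (gamma_w, theta_w) and the
neat organic, which wets nearly everything so gamma*cos(theta) ~ gamma_alc.
The line's slope changes sign at the critical water contact angle
cos(theta_wc) = gamma_alc/gamma_w (~72 deg for ethanol/water): below it
alcohol weakens the adhesion tension, above it alcohol strengthens it.

Composition profiles combine this adhesion law with a fitted surface
tension curve gamma(x) (x = organic mole fraction) and the two-state
monolayer adsorption model of :mod:`monowet.thermo`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit

from .errors import AlwaysAdsorbsError, DomainError, NeverAdsorbsError
from .thermo import (
    DEFAULT_MODEL,
    AdhesionModel,
    SubstrateState,
    solve_adsorption_angle,
)

__all__ = [
    "ZismanLine",
    "MixtureCurve",
    "zisman_adhesion_tension",
    "zisman_from_endpoints",
    "critical_water_angle",
    "fit_mixture_tension",
    "theta_ads_profile",
    "free_energy_profile",
]

#: Mole fraction beyond which lipids dissolve into micelles and the
#: two-state (adsorbed monolayer vs. bulk bilayer) picture breaks down.
DEFAULT_SOLUBILITY_LIMIT = 0.20


@dataclass(frozen=True)
class ZismanLine:
    """Adhesion-tension line gamma*cos(theta) = c0 + c1*gamma for one solid."""

    c0: float  # mN/m
    c1: float  # dimensionless

    def adhesion_tension(self, gamma: float) -> float:
        return self.c0 + self.c1 * gamma


def zisman_adhesion_tension(gamma, line: ZismanLine):
    """Evaluate the adhesion-tension line at surface tension ``gamma`` (mN/m)."""
    if np.any(np.asarray(gamma) <= 0):
        raise DomainError("gamma must be positive")
    return line.c0 + line.c1 * np.asarray(gamma)


def zisman_from_endpoints(
    gamma_w: float, theta_w: float, gamma_alc: float
) -> ZismanLine:
    """Adhesion-tension line from the two reference states.

    Neat water pins (gamma_w, gamma_w*cos(theta_w)); the neat organic pins
    (gamma_alc, gamma_alc) because it wets nearly completely.  Solving the
    two conditions gives

        c1 = (gamma_w*cos(theta_w) - gamma_alc) / (gamma_w - gamma_alc)
        c0 = gamma_alc * (1 - c1)
    """
    if gamma_w == gamma_alc:
        raise DomainError("endpoint surface tensions must differ")
    if not 0.0 <= theta_w <= 180.0:
        raise DomainError(f"theta_w={theta_w!r} outside [0, 180] degrees")
    c1 = (gamma_w * math.cos(math.radians(theta_w)) - gamma_alc) / (gamma_w - gamma_alc)
    return ZismanLine(c0=gamma_alc * (1.0 - c1), c1=c1)


def critical_water_angle(gamma_w: float, gamma_alc: float) -> float:
    """Water contact angle with composition-independent adhesion tension.

    cos(theta_wc) = gamma_alc/gamma_w; at this angle the Zisman line is
    flat (c1 = 0) and gamma*cos(theta) = gamma_alc at every composition.
    Returns degrees.
    """
    if not 0 < gamma_alc <= gamma_w:
        raise DomainError(
            f"need 0 < gamma_alc <= gamma_w, got ({gamma_alc!r}, {gamma_w!r})"
        )
    return math.degrees(math.acos(gamma_alc / gamma_w))


def _exp_decay(x, gamma_w, gamma_alc, ell):
    """Normalized exponential decay from gamma_w at x=0 to gamma_alc at x=1."""
    span = np.expm1(-1.0 / ell)
    return gamma_alc + (gamma_w - gamma_alc) * (np.expm1(-x / ell) - span) / (0.0 - span)


@dataclass(frozen=True)
class MixtureCurve:
    """Surface tension of a binary mixture as a function of mole fraction.

    ``gamma_of_x`` is a monotone interpolant/fit through the supplied
    (x, gamma) table.  ``solubility_limit`` marks the composition beyond
    which the downstream two-state model is flagged as unreliable.
    """

    x: np.ndarray
    gamma: np.ndarray
    gamma_of_x: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    solubility_limit: float = DEFAULT_SOLUBILITY_LIMIT
    kind: str = "pchip"

    def __call__(self, x):
        return self.gamma_of_x(np.asarray(x, dtype=float))

    @property
    def gamma_w(self) -> float:
        """Surface tension of the aqueous endpoint, gamma(0)."""
        return float(self.gamma_of_x(0.0))

    @property
    def gamma_alc(self) -> float:
        """Surface tension of the organic endpoint, gamma(1)."""
        return float(self.gamma_of_x(1.0))


def fit_mixture_tension(
    x,
    gamma,
    *,
    kind: Literal["pchip", "linear", "exponential"] = "pchip",
    solubility_limit: float = DEFAULT_SOLUBILITY_LIMIT,
    exclude=None,
) -> MixtureCurve:
    """Fit a monotone gamma(x) curve to a binary-mixture tension table.

    Parameters
    ----------
    x, gamma : array-like
        Mole fractions (strictly increasing, within [0, 1]) and surface
        tensions (mN/m, positive).  At least 3 points.
    kind : str
        ``"pchip"`` (default): shape-preserving piecewise-cubic interpolant,
        exact at the data and free of overshoot.  ``"linear"``: piecewise
        linear.  ``"exponential"``: three-parameter smooth decay
        gamma_alc + (gamma_w - gamma_alc)*f(x; ell), useful for noisy data.
    exclude : array-like of bool, optional
        Per-point exclusion mask (True drops the point before fitting),
        for off-trend measurements.
    """
    x = np.asarray(x, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        x, gamma = x[keep], gamma[keep]
    if x.size < 3 and kind != "linear":
        raise DomainError(f"need at least 3 points, got {x.size}")
    if x.size < 2:
        raise DomainError(f"need at least 2 points, got {x.size}")
    if np.any(np.diff(x) <= 0):
        raise DomainError("x must be strictly increasing")
    if x[0] < 0 or x[-1] > 1:
        raise DomainError("x must lie within [0, 1]")
    if np.any(gamma <= 0):
        raise DomainError("gamma must be positive")

    if np.any(np.diff(gamma) > 0) and kind != "exponential":
        warnings.warn(
            "gamma(x) data not monotone non-increasing; applying isotonic "
            "pre-smoothing before interpolation",
            stacklevel=2,
        )
        from sklearn.isotonic import IsotonicRegression

        gamma = IsotonicRegression(increasing=False).fit_transform(x, gamma)

    if kind == "pchip":
        interp = PchipInterpolator(x, gamma, extrapolate=True)
        gamma_of_x = lambda xv: np.asarray(interp(xv), dtype=float)  # noqa: E731
    elif kind == "linear":
        gamma_of_x = lambda xv: np.interp(xv, x, gamma)  # noqa: E731
    elif kind == "exponential":
        p0 = (gamma[0], gamma[-1], 0.2)
        popt, _ = curve_fit(
            _exp_decay, x, gamma, p0=p0, bounds=([1.0, 1.0, 1e-3], [500.0, 500.0, 10.0])
        )
        gamma_of_x = lambda xv: np.asarray(_exp_decay(xv, *popt), dtype=float)  # noqa: E731
    else:
        raise DomainError(f"unknown fit kind {kind!r}")

    return MixtureCurve(
        x=x, gamma=gamma, gamma_of_x=gamma_of_x,
        solubility_limit=solubility_limit, kind=kind,
    )


def _composition_frame(curve: MixtureCurve, x_grid) -> tuple[np.ndarray, np.ndarray, list[str]]:
    x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
    if np.any((x_grid < 0) | (x_grid > 1)):
        raise DomainError("x_grid must lie within [0, 1]")
    gam = np.asarray(curve(x_grid), dtype=float)
    flags = [
        "beyond_solubility_limit" if xv > curve.solubility_limit else ""
        for xv in x_grid
    ]
    return x_grid, gam, flags


def theta_ads_profile(
    curve: MixtureCurve,
    model: AdhesionModel = DEFAULT_MODEL,
    x_grid=None,
) -> pd.DataFrame:
    """Adsorption contact angle versus mixture composition.

    For each mole fraction x the implicit threshold condition
    cos(theta_ads) = (2*wsl(theta_ads) - wll) / (2*gamma(x)) is solved with
    the solvent entering only through gamma(x); the works of adhesion are
    held solvent-independent.  Where the right-hand side exceeds 1 the
    threshold has collapsed to zero (every substrate adsorbs) and the row
    is marked ``always_adsorbs`` with theta_ads = 0.

    Returns a DataFrame with columns
    ``x, gamma_mN_per_m, theta_ads_deg, flag``.
    """
    if x_grid is None:
        x_grid = np.linspace(0.0, curve.solubility_limit, 21)
    x_grid, gam, flags = _composition_frame(curve, x_grid)
    theta = np.empty_like(gam)
    for i, g in enumerate(gam):
        try:
            theta[i] = solve_adsorption_angle(model, float(g))
        except AlwaysAdsorbsError:
            theta[i] = 0.0
            flags[i] = (flags[i] + ";" if flags[i] else "") + "always_adsorbs"
        except NeverAdsorbsError:
            theta[i] = np.nan
            flags[i] = (flags[i] + ";" if flags[i] else "") + "never_adsorbs"
    return pd.DataFrame(
        {"x": x_grid, "gamma_mN_per_m": gam, "theta_ads_deg": theta, "flag": flags}
    )


def free_energy_profile(
    curve: MixtureCurve,
    substrate: SubstrateState,
    model: AdhesionModel = DEFAULT_MODEL,
    gamma_alc: float | None = None,
    x_grid=None,
    theta_eval: float | None = None,
) -> pd.DataFrame:
    """Monolayer adsorption free energy versus mixture composition.

    The adhesion tension gamma*cos(theta) at each composition comes from
    the substrate's two-endpoint adhesion line (built from its water
    contact angle and the organic endpoint), evaluated at gamma(x).  The
    works of adhesion are solvent-independent; the weakly theta-dependent
    wsl is evaluated at ``theta_eval`` (default: the in-water adsorption
    contact angle), so all substrates share one neat-organic limit
    wll/2 - wsl + gamma_alc.

    Rows beyond the solubility limit are flagged ``beyond_solubility_limit``
    (micellization: the two-state model breaks down) but still computed.

    Returns a DataFrame with columns
    ``x, gamma_mN_per_m, adhesion_tension_mN_per_m, free_energy_mN_per_m, flag``.
    """
    if gamma_alc is None:
        gamma_alc = curve.gamma_alc
    if x_grid is None:
        x_grid = np.linspace(0.0, curve.solubility_limit, 21)
    gamma_w = curve.gamma_w
    line = zisman_from_endpoints(gamma_w, substrate.theta_w, gamma_alc)
    if theta_eval is None:
        theta_eval = solve_adsorption_angle(model, gamma_w)
    x_grid, gam, flags = _composition_frame(curve, x_grid)
    adhesion = line.c0 + line.c1 * gam
    dfa = model.wll / 2.0 - model.wsl(theta_eval) + adhesion
    return pd.DataFrame(
        {
            "x": x_grid,
            "gamma_mN_per_m": gam,
            "adhesion_tension_mN_per_m": adhesion,
            "free_energy_mN_per_m": dfa,
            "flag": flags,
        }
    )
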