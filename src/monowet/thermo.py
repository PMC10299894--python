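"""Two-state thermodynamics of lipid monolayer adsorption on solid surfaces.

The model compares a lipid bilayer dispersed in solution with a monolayer
adsorbed on a solid substrate characterized by its water contact angle
``theta`` (degrees).  Per unit monolayer area the adsorption free energy is

    dF/A = w_ll/2 - w_sl(theta) + gamma*cos(theta)        [mN/m]

where ``w_ll`` is the lipid-lipid work of adhesion of the two bilayer
leaflets across vacuum, ``w_sl(theta)`` the substrate-lipid work of adhesion
(weakly, nearly linearly dependent on substrate polarity and hence on
``theta``), and ``gamma*cos(theta)`` the solvent adhesion tension removed
from the substrate patch the monolayer covers.  The *adsorption contact
angle* ``theta_ads`` is the root dF(theta_ads) = 0: substrates with
``theta > theta_ads`` favor the adsorbed monolayer.

All tensions are in mN/m and all angles in degrees at the interface;
radians appear only inside trigonometric calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import (
    AlwaysAdsorbsError,
    DomainError,
    NeverAdsorbsError,
    NoEquivalentAngleError,
)

__all__ = [
    "AdhesionModel",
    "SolventState",
    "SubstrateState",
    "FreeEnergyBreakdown",
    "DEFAULT_MODEL",
    "wsl_at",
    "adsorption_free_energy",
    "solve_adsorption_angle",
    "theta_ads_hydrocarbon",
    "linearized_free_energy",
    "air_water_free_energy",
    "equivalent_contact_angle",
    "neat_organic_free_energy",
    "round_half_away",
]

#: Water-vapor surface tension at room temperature, mN/m.
GAMMA_WATER = 72.0
#: Ethanol-vapor surface tension at room temperature, mN/m.
GAMMA_ETHANOL = 22.0

# Root-finding controls: free-energy residual tolerance (mN/m) and the
# scan resolution (degrees) used for sign-change bracketing.
_FTOL = 1e-9
_SCAN_STEP = 0.1


def _cosd(theta: float) -> float:
    return math.cos(math.radians(theta))


def round_half_away(value: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used for headline values reported at integer precision (degrees, mN/m),
    where banker's rounding would be surprising.
    """
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


def _check_angle(theta: float, name: str = "theta") -> None:
    if not 0.0 <= theta <= 180.0:
        raise DomainError(f"{name}={theta!r} outside [0, 180] degrees")


@dataclass(frozen=True)
class AdhesionModel:
    """Lipid-lipid adhesion plus a linear substrate-lipid adhesion law.

    Parameters
    ----------
    wll : float
        Work of adhesion for separating the two bilayer leaflets across
        vacuum, mN/m.  Must be positive.
    wsl_intercept : float
        Substrate-lipid work of adhesion extrapolated to a completely
        wetting substrate (theta = 0 degrees), mN/m.
    wsl_slope : float
        d(w_sl)/d(theta), mN/m per degree; typically a small negative
        number because polar substrates adhere slightly more strongly to
        the weakly polar lipid tails.

    The default constructed by :data:`DEFAULT_MODEL` passes the line
    through (0 deg, 57 mN/m) and (113 deg, 52 mN/m) with wll = 49 mN/m,
    the values measured for DLPC on an alkyl self-assembled monolayer.
    """

    wll: float = 49.0
    wsl_intercept: float = 57.0
    wsl_slope: float = (52.0 - 57.0) / 113.0

    def __post_init__(self) -> None:
        if self.wll <= 0:
            raise DomainError(f"wll must be positive, got {self.wll!r}")
        # w_sl must stay positive over the whole admissible angle range.
        if min(self.wsl(0.0), self.wsl(180.0)) <= 0:
            raise DomainError(
                "wsl(theta) must be positive on [0, 180] degrees; got "
                f"wsl(0)={self.wsl(0.0):.3f}, wsl(180)={self.wsl(180.0):.3f}"
            )

    @classmethod
    def from_wsl_points(
        cls, p1: tuple[float, float], p2: tuple[float, float], wll: float = 49.0
    ) -> "AdhesionModel":
        """Build the linear w_sl(theta) law through two (theta, wsl) anchors."""
        (t1, w1), (t2, w2) = p1, p2
        if t1 == t2:
            raise DomainError("wsl anchor angles must differ")
        slope = (w2 - w1) / (t2 - t1)
        return cls(wll=wll, wsl_intercept=w1 - slope * t1, wsl_slope=slope)

    def wsl(self, theta: float) -> float:
        """Substrate-lipid work of adhesion at contact angle ``theta`` (deg)."""
        _check_angle(theta)
        return self.wsl_intercept + self.wsl_slope * theta


#: The default parametrization from the MD measurements (see class docstring).
DEFAULT_MODEL = AdhesionModel()


@dataclass(frozen=True)
class SolventState:
    """A solvent described by its liquid-vapor surface tension (mN/m)."""

    gamma: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise DomainError(f"gamma must be positive, got {self.gamma!r}")


@dataclass(frozen=True)
class SubstrateState:
    """A solid substrate characterized by its water contact angle (degrees)."""

    theta_w: float
    name: str = ""

    def __post_init__(self) -> None:
        _check_angle(self.theta_w, "theta_w")


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Adsorption free energy per area and its three contributions (mN/m).

    ``total`` is stored as the exact sum of the three terms, so the
    breakdown is additive by construction.
    """

    term_ll: float
    term_sl: float
    term_adhesion: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "total", self.term_ll + self.term_sl + self.term_adhesion
        )


def wsl_at(model: AdhesionModel, theta: float) -> float:
    """Substrate-lipid work of adhesion w_sl(theta), mN/m (theta in degrees)."""
    return model.wsl(theta)


def adsorption_free_energy(
    theta: float, model: AdhesionModel = DEFAULT_MODEL, gamma: float = GAMMA_WATER
) -> FreeEnergyBreakdown:
    """Monolayer adsorption free energy per area at contact angle ``theta``.

    Returns the term-by-term breakdown of
    dF/A = wll/2 - wsl(theta) + gamma*cos(theta).
    Positive total: the bulk bilayer is preferred (no monolayer forms);
    negative: the adsorbed monolayer is stable.
    """
    _check_angle(theta)
    if gamma <= 0:
        raise DomainError(f"gamma must be positive, got {gamma!r}")
    return FreeEnergyBreakdown(
        term_ll=model.wll / 2.0,
        term_sl=-model.wsl(theta),
        term_adhesion=gamma * _cosd(theta),
    )


def _bisect(f, lo: float, hi: float, ftol: float = _FTOL) -> float:
    """Plain bisection for a sign change of ``f`` on [lo, hi].

    Iterates until the function residual at the midpoint is below ``ftol``
    or the bracket collapses to floating-point resolution.
    """
    flo = f(lo)
    if flo == 0.0:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if abs(fmid) < ftol or (hi - lo) < 1e-14:
            return mid
        if (fmid > 0) == (flo > 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _bracketed_roots(f, lo: float = 0.0, hi: float = 180.0, step: float = _SCAN_STEP):
    """All sign-change brackets of ``f`` on a uniform scan of [lo, hi]."""
    n = int(round((hi - lo) / step))
    brackets = []
    t_prev, f_prev = lo, f(lo)
    for i in range(1, n + 1):
        t = lo + (hi - lo) * i / n
        ft = f(t)
        if f_prev == 0.0:
            brackets.append((t_prev, t_prev))
        elif ft == 0.0 and i == n:
            brackets.append((t, t))
        elif (f_prev > 0) != (ft > 0):
            brackets.append((t_prev, t))
        t_prev, f_prev = t, ft
    return brackets


def _solve_angle_equation(f, what: str) -> float:
    """Smallest root of ``f`` on [0, 180] deg by scan + bisection.

    Raises a typed error when no sign change exists; warns when the scan
    finds several roots (the smallest is returned).
    """
    brackets = _bracketed_roots(f)
    if not brackets:
        if f(90.0) > 0:
            raise NeverAdsorbsError(
                f"{what}: free energy positive over [0, 180] deg "
                "(bilayer preferred on every substrate)"
            )
        raise AlwaysAdsorbsError(
            f"{what}: free energy negative over [0, 180] deg "
            "(monolayer preferred on every substrate)"
        )
    if len(brackets) > 1:
        warnings.warn(
            f"{what}: {len(brackets)} sign changes found on [0, 180] deg; "
            "returning the smallest root",
            stacklevel=3,
        )
    lo, hi = brackets[0]
    return lo if lo == hi else _bisect(f, lo, hi)


def solve_adsorption_angle(
    model: AdhesionModel = DEFAULT_MODEL, gamma: float = GAMMA_WATER
) -> float:
    """Adsorption contact angle theta_ads (degrees).

    The root of dF/A(theta) = 0 on [0, 180] degrees, located by sign-change
    scanning followed by bisection to a free-energy residual below 1e-9
    mN/m.  Equivalently the fixed point of
    cos(theta_ads) = (2*wsl(theta_ads) - wll) / (2*gamma).

    Raises
    ------
    NeverAdsorbsError
        dF > 0 everywhere: no substrate can hold a stable monolayer.
    AlwaysAdsorbsError
        dF < 0 everywhere: every substrate holds a stable monolayer.
    """
    if gamma <= 0:
        raise DomainError(f"gamma must be positive, got {gamma!r}")

    def f(theta: float) -> float:
        return adsorption_free_energy(theta, model, gamma).total

    return _solve_angle_equation(f, "solve_adsorption_angle")


def theta_ads_hydrocarbon(
    gamma_hc: float, gamma: float = GAMMA_WATER, theta_hc: float = 0.0
) -> float:
    """Hydrocarbon-liquid estimate of the adsorption contact angle (degrees).

    Treating the lipid tails as a bulk hydrocarbon liquid gives
    wll ~ 2*gamma_hc and wsl = gamma_hc*(1 + cos(theta_hc)), which reduces
    the threshold condition to cos(theta_ads) = gamma_hc*cos(theta_hc)/gamma.
    With ``theta_hc = 0`` (hydrocarbons wet most solids) this is simply the
    ratio of the hydrocarbon and solvent surface tensions.
    """
    _check_angle(theta_hc, "theta_hc")
    if gamma <= 0:
        raise DomainError(f"gamma must be positive, got {gamma!r}")
    ratio = gamma_hc * _cosd(theta_hc) / gamma
    if ratio <= 0:
        raise DomainError(
            f"gamma_hc*cos(theta_hc)={gamma_hc * _cosd(theta_hc):.3f} must be positive"
        )
    if ratio > 1:
        raise DomainError(
            "no adsorption threshold: solvent tension below the hydrocarbon "
            f"wetting tension (ratio {ratio:.3f} > 1)"
        )
    return math.degrees(math.acos(ratio))


def linearized_free_energy(
    theta: float, theta_ads: float, gamma: float = GAMMA_WATER
) -> float:
    """Linearized adsorption free energy gamma*(cos theta - cos theta_ads).

    Obtained by freezing wsl at its value at the threshold angle; exact at
    theta = theta_ads and accurate to |wsl_slope|*|theta - theta_ads|
    elsewhere.
    """
    _check_angle(theta)
    _check_angle(theta_ads, "theta_ads")
    if gamma <= 0:
        raise DomainError(f"gamma must be positive, got {gamma!r}")
    return gamma * (_cosd(theta) - _cosd(theta_ads))


def air_water_free_energy(
    model: AdhesionModel = DEFAULT_MODEL, gamma: float = GAMMA_WATER
) -> float:
    """Monolayer adsorption free energy at the air-water interface (mN/m).

    The air phase is a perfectly hydrophobic substrate with no lipid
    adhesion: theta = 180 degrees and wsl = 0, so dF/A = wll/2 - gamma.
    Negative for water: the Langmuir monolayer beats the bulk bilayer.
    """
    if gamma <= 0:
        raise DomainError(f"gamma must be positive, got {gamma!r}")
    return model.wll / 2.0 - gamma


def equivalent_contact_angle(
    model: AdhesionModel = DEFAULT_MODEL, gamma: float = GAMMA_WATER
) -> float:
    """Contact angle of a solid matching the air-water adsorption strength.

    Solves the implicit equation cos(theta*) = wsl(theta*)/gamma - 1 with
    the same scan-plus-bisection machinery as the threshold solver.  Solids
    with theta > theta* adsorb monolayers more strongly than the air-water
    interface does.
    """
    if gamma <= 0:
        raise DomainError(f"gamma must be positive, got {gamma!r}")

    def f(theta: float) -> float:
        return _cosd(theta) - (model.wsl(theta) / gamma - 1.0)

    try:
        return _solve_angle_equation(f, "equivalent_contact_angle")
    except (NeverAdsorbsError, AlwaysAdsorbsError) as exc:
        raise NoEquivalentAngleError(
            "cos(theta) = wsl(theta)/gamma - 1 has no root in [0, 180] deg"
        ) from exc


def neat_organic_free_energy(
    model: AdhesionModel = DEFAULT_MODEL,
    gamma_alc: float = GAMMA_ETHANOL,
    theta_eval: float | None = None,
) -> float:
    """Adsorption free energy in the hypothetical neat-organic limit (mN/m).

    In a neat organic solvent the adhesion tension saturates at the
    solvent's own surface tension (cos theta -> 1), so
    dF/A = wll/2 - wsl + gamma_alc, nearly independent of the substrate.
    ``theta_eval`` picks the angle at which the weakly varying wsl is
    evaluated; the default is the in-water adsorption contact angle.
    """
    if gamma_alc <= 0:
        raise DomainError(f"gamma_alc must be positive, got {gamma_alc!r}")
    if theta_eval is None:
        theta_eval = solve_adsorption_angle(model, GAMMA_WATER)
    return model.wll / 2.0 - model.wsl(theta_eval) + gamma_alc
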