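"""Work of adhesion from pressure-distance curves.

Separating two condensed surfaces (two bilayer leaflets, or a monolayer
from its substrate) reversibly at separation D costs the work

    w = -integral_{D_contact}^{infinity} P(D) dD,

where P(D) is the interaction pressure (negative = attractive, in bar as
MD codes report it) and D_contact the equilibrium contact separation.  The
sampled part of the curve is integrated by the trapezoid rule; the
unsampled attractive tail can optionally be extended to infinity with a
power-law fit P ~ -C/D^n to the outermost points (dispersion tails decay
slowly).  Results are converted to mN/m (1 bar*nm = 0.1 mN/m); a positive
w means the surfaces adhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DomainError

__all__ = [
    "PressureDistanceCurve",
    "work_of_adhesion",
    "convert_pressure_length",
    "BAR_NM_TO_MN_PER_M",
]

#: 1 bar*nm = 1e5 Pa * 1e-9 m = 1e-4 J/m^2 = 0.1 mN/m, exactly.
BAR_NM_TO_MN_PER_M = 0.1


def convert_pressure_length(value):
    """Convert bar*nm to mN/m (exact factor 0.1)."""
    return np.multiply(value, BAR_NM_TO_MN_PER_M)


def _auto_contact(D: np.ndarray, P: np.ndarray) -> float:
    """Default lower integration bound: the pressure zero-crossing nearest
    the minimum of the running integral of P (the equilibrium contact
    separation between the repulsive core and the attractive well)."""
    from scipy.integrate import cumulative_trapezoid

    run = cumulative_trapezoid(P, D, initial=0.0)
    d_min = D[int(np.argmin(run))]
    sign_change = np.nonzero(np.diff(np.sign(P)) != 0)[0]
    if sign_change.size == 0:
        return float(D[0])
    crossings = []
    for i in sign_change:
        d0, d1, p0, p1 = D[i], D[i + 1], P[i], P[i + 1]
        crossings.append(d0 if p1 == p0 else d0 - p0 * (d1 - d0) / (p1 - p0))
    crossings = np.asarray(crossings)
    return float(crossings[np.argmin(np.abs(crossings - d_min))])


@dataclass(frozen=True)
class PressureDistanceCurve:
    """Sampled interaction pressure P(D) between two separating surfaces.

    ``D`` in nm, strictly increasing; ``P`` in bar, negative where the
    surfaces attract.  ``D_contact`` is the lower integration bound; if
    omitted it is placed at the pressure zero-crossing nearest the minimum
    of the running integral.
    """

    D: np.ndarray
    P: np.ndarray
    D_contact: float | None = None

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        P = np.asarray(self.P, dtype=float)
        if D.ndim != 1 or D.size != P.size or D.size < 3:
            raise DomainError("D and P must be 1-D arrays of equal length >= 3")
        if np.any(np.diff(D) <= 0):
            raise DomainError("D must be strictly increasing")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "P", P)
        dc = self.D_contact
        if dc is None:
            dc = _auto_contact(D, P)
        if dc < D[0] or dc >= D[-1]:
            raise DomainError(
                f"D_contact={dc!r} outside the sampled range [{D[0]}, {D[-1]})"
            )
        object.__setattr__(self, "D_contact", float(dc))


def _tail_fit(D: np.ndarray, P: np.ndarray, n_tail: int) -> tuple[float, float]:
    """Fit P ~ -C/D^n to the outermost points; returns (C, n)."""
    Dt, Pt = D[-n_tail:], P[-n_tail:]
    if np.any(Pt >= 0):
        raise DomainError("tail fit requires strictly attractive (P < 0) tail points")
    slope, logC = np.polyfit(np.log(Dt), np.log(-Pt), 1)
    n = -float(slope)
    if n <= 1.0:
        raise DomainError(
            f"fitted tail exponent n={n:.3f} <= 1: tail integral diverges"
        )
    return float(math.exp(logC)), n


def work_of_adhesion(
    curve: PressureDistanceCurve,
    tail: Literal["none", "power"] = "none",
    tail_fraction: float = 0.25,
) -> float:
    """Work of adhesion (mN/m) by trapezoid integration of -P(D).

    Integrates from ``curve.D_contact`` to the last sampled separation,
    interpolating the pressure at the contact bound.  With
    ``tail="power"`` a power law -C/D^n is fitted to the outermost
    ``tail_fraction`` of points (at least 4) and its analytic integral
    C*D_max^(1-n)/(n-1) extends the result to infinite separation.
    Positive values mean the surfaces adhere.
    """
    D, P = curve.D, curve.P
    dc = curve.D_contact
    mask = D > dc
    Dint = np.concatenate(([dc], D[mask]))
    Pint = np.concatenate(([np.interp(dc, D, P)], P[mask]))
    w_bar_nm = -np.trapezoid(Pint, Dint)
    if tail == "power":
        n_tail = max(4, int(round(tail_fraction * D.size)))
        if n_tail > D.size:
            raise DomainError("not enough points for the requested tail fit")
        C, n = _tail_fit(D, P, n_tail)
        # -integral_{Dmax}^{inf} (-C D^-n) dD = -C*Dmax^(1-n)/(n-1), so the
        # tail adds +C*Dmax^(1-n)/(n-1) to the work.
        w_bar_nm += C * D[-1] ** (1.0 - n) / (n - 1.0)
    elif tail != "none":
        raise DomainError(f"unknown tail option {tail!r}")
    return float(convert_pressure_length(w_bar_nm))
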