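"""Seeded generators for every input the analysis pipeline consumes.

Each generator returns the data object together with a machine-readable
truth record (a plain dict) holding the generating parameters, so
round-trip tests (generate -> analyze -> compare) need no external data.
Identical parameters and seed give bit-identical output.

What is emulated, and what is not: droplet density maps are ideal circular
caps with a smooth tanh interface plus optional uncorrelated Gaussian
noise — they carry no near-wall density layering, capillary-wave
broadening or finite sampling correlation; pressure-distance curves are
smooth Lennard-Jones-like (9-3) or single power laws with closed-form
integrals; mixture tables follow an exponential-type tension decay with
adhesion tensions generated exactly from the two-endpoint Zisman line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .adhesion import BAR_NM_TO_MN_PER_M, PressureDistanceCurve
from .droplet import DensityField
from .errors import DomainError
from .mixtures import zisman_from_endpoints

__all__ = [
    "SyntheticSpec",
    "make_droplet_field",
    "make_droplet_series",
    "make_pd_curve",
    "make_mixture_table",
]

#: Bulk density of liquid water at ambient conditions, molecules/nm^3.
RHO_WATER = 33.4


@dataclass(frozen=True)
class SyntheticSpec:
    """A reproducible recipe: generator kind, parameters, and seed."""

    kind: Literal["droplet", "pd_curve", "mixture_table"]
    seed: int = 0
    parameters: dict = field(default_factory=dict)

    def make(self):
        if self.kind == "droplet":
            return make_droplet_field(seed=self.seed, **self.parameters)
        if self.kind == "pd_curve":
            return make_pd_curve(seed=self.seed, **self.parameters)
        if self.kind == "mixture_table":
            return make_mixture_table(seed=self.seed, **self.parameters)
        raise DomainError(f"unknown synthetic kind {self.kind!r}")


def make_droplet_field(
    theta_true: float,
    R: float,
    width: float = 0.4,
    dy: float = 0.1,
    dz: float = 0.1,
    z0: float = 1.0,
    rho_bulk: float = RHO_WATER,
    noise_sd: float = 0.0,
    pad: float = 2.0,
    seed: int | None = None,
) -> tuple[DensityField, dict]:
    """Density map of a cylindrical circular-cap droplet with known angle.

    The cap is the circle of radius ``R`` whose center sits at
    zc = z0 - R*cos(theta_true), so the plane z = z0 cuts it at exactly
    ``theta_true`` (degrees).  The density decays across the interface as
    rho_bulk * (1 - tanh(2*(d - R)/width)) / 2 with d the distance from
    the center, placing the half-density contour exactly on the true
    circle; ``width`` sets the diffuse-interface scale (10-90 density
    distance ~ 1.1*width).  Below the substrate plane the density is zero.
    Optional additive Gaussian noise (sd in density units) is clipped at
    zero to keep the map physical.
    """
    if not 0.0 < theta_true < 180.0:
        raise DomainError(f"theta_true={theta_true!r} outside (0, 180)")
    if width <= 0 or R < 3.0 * width:
        raise DomainError("need width > 0 and R >= 3*width for a resolved cap")
    cos_t = math.cos(math.radians(theta_true))
    zc = z0 - R * cos_t
    if zc + R <= z0:
        raise DomainError("cap lies entirely below the substrate plane")
    half_width = R * math.sin(math.radians(theta_true)) + pad
    height = (zc + R - z0) + pad
    y = np.arange(-half_width, half_width + dy / 2, dy)
    z = np.arange(0.0, z0 + height + dz / 2, dz)
    yy, zz = np.meshgrid(y, z)
    d = np.hypot(yy - 0.0, zz - zc)
    rho = rho_bulk * 0.5 * (1.0 - np.tanh(2.0 * (d - R) / width))
    rho[zz < z0] = 0.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rho = rho + rng.normal(0.0, noise_sd, size=rho.shape)
    rho = np.clip(rho, 0.0, None)
    field = DensityField(
        grid=rho, dy=dy, dz=dz, z0=z0, rho_bulk=rho_bulk,
        y_min=float(y[0]), z_min=float(z[0]),
    )
    truth = {
        "theta_true_deg": theta_true, "R_nm": R, "yc_nm": 0.0, "zc_nm": zc,
        "z0_nm": z0, "width_nm": width, "rho_bulk": rho_bulk,
        "noise_sd": noise_sd, "seed": seed,
    }
    return field, truth


def make_droplet_series(
    theta_inf: float,
    radii: Sequence[float],
    bias_nm: float = 0.0,
    seed: int | None = None,
    **kwargs,
) -> tuple[list[tuple[DensityField, dict]], dict]:
    """Droplets of several sizes with a 1/R finite-size bias on cos(theta).

    Each droplet of radius R is generated with
    cos(theta_true(R)) = cos(theta_inf) + bias_nm / R, emulating the
    curvature-dependent angles of small simulated droplets; extrapolating
    the measured angles against 1/R should recover ``theta_inf``.
    """
    cos_inf = math.cos(math.radians(theta_inf))
    out = []
    seq = np.random.SeedSequence(seed) if seed is not None else None
    for i, R in enumerate(radii):
        c = cos_inf + bias_nm / R
        if abs(c) >= 1.0:
            raise DomainError(f"bias drives cos(theta) out of range at R={R}")
        sub_seed = None if seq is None else int(seq.spawn(1)[0].generate_state(1)[0] % 2**31)
        out.append(
            make_droplet_field(math.degrees(math.acos(c)), R, seed=sub_seed, **kwargs)
        )
    truth = {"theta_inf_deg": theta_inf, "bias_nm": bias_nm, "radii_nm": list(radii)}
    return out, truth


def make_pd_curve(
    form: Literal["9-3", "power"] = "9-3",
    eps: float = 100.0,
    sigma: float = 1.0,
    C: float = 1.0,
    n: float = 3.0,
    n_points: int = 200,
    D_range: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[PressureDistanceCurve, dict]:
    """Sampled pressure-distance curve with a closed-form work of adhesion.

    ``"9-3"``: P(D) = eps*((sigma/D)^9 - (sigma/D)^3) bar — repulsive core,
    attractive dispersion tail, contact (zero crossing) at D = sigma; the
    exact work from contact to infinity is 3*eps*sigma/8 bar*nm.
    ``"power"``: P(D) = -C/D^n bar (n > 1), exact work from D0 = D_range[0]
    of C*D0^(1-n)/(n-1) bar*nm.  The attached truth record stores the
    analytic work in mN/m.
    """
    if form == "9-3":
        if eps <= 0 or sigma <= 0:
            raise DomainError("9-3 form needs eps > 0 and sigma > 0")
        if D_range is None:
            D_range = (0.8 * sigma, 12.0 * sigma)
        D = np.linspace(*D_range, n_points)
        P = eps * ((sigma / D) ** 9 - (sigma / D) ** 3)
        d_contact = sigma
        work_bar_nm = 3.0 * eps * sigma / 8.0
    elif form == "power":
        if C < 0:
            raise DomainError("power form needs C >= 0")
        if C > 0 and n <= 1:
            raise DomainError(f"power-law exponent n={n!r} <= 1 is non-integrable")
        if D_range is None:
            D_range = (1.0, 20.0)
        D = np.linspace(*D_range, n_points)
        P = -C / D**n
        d_contact = D_range[0]
        work_bar_nm = 0.0 if C == 0 else C * d_contact ** (1.0 - n) / (n - 1.0)
    else:
        raise DomainError(f"unknown pressure-distance form {form!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        P = P + rng.normal(0.0, noise_sd, size=P.shape)
    curve = PressureDistanceCurve(D=D, P=P, D_contact=d_contact)
    truth = {
        "form": form, "analytic_work_mN_per_m": work_bar_nm * BAR_NM_TO_MN_PER_M,
        "D_contact_nm": d_contact, "n_points": n_points, "noise_sd": noise_sd,
        "seed": seed,
    }
    return curve, truth


def _gamma_shape(x: np.ndarray, gamma_w: float, gamma_alc: float,
                 shape: str, ell: float, beta: float) -> np.ndarray:
    if shape == "linear":
        f = 1.0 - x
    elif shape == "exponential":
        f = (np.exp(-x / ell) - math.exp(-1.0 / ell)) / (1.0 - math.exp(-1.0 / ell))
    elif shape == "stretched":
        f = (np.exp(-((x / ell) ** beta)) - math.exp(-((1.0 / ell) ** beta))) / (
            1.0 - math.exp(-((1.0 / ell) ** beta))
        )
    else:
        raise DomainError(f"unknown shape {shape!r}")
    return gamma_alc + (gamma_w - gamma_alc) * f


def make_mixture_table(
    gamma_w: float = 72.0,
    gamma_alc: float = 22.0,
    shape: Literal["linear", "exponential", "stretched"] = "exponential",
    n_points: int = 21,
    theta_w_list: Sequence[float] = (45.0, 66.0, 104.0),
    noise_sd: float = 0.0,
    ell: float = 0.17,
    beta: float = 0.8,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Surface-tension and wetting table for a water/organic mixture.

    gamma(x) decays monotonically from ``gamma_w`` to ``gamma_alc`` with
    the chosen shape (default exponential with decay scale ``ell`` in mole
    fraction, matching the steep initial drop of ethanol/water tension);
    for each substrate water contact angle in ``theta_w_list`` the
    adhesion tension and cos(theta) columns are generated exactly from the
    two-endpoint Zisman line, with optional Gaussian noise (mN/m) added to
    both gamma and the adhesion tensions.

    Returns a DataFrame with columns ``x, gamma_mN_per_m`` and, per
    substrate, ``adh_tension_<thetaw>`` and ``cos_theta_<thetaw>``, plus a
    truth record with the generating parameters and Zisman coefficients.
    """
    if not gamma_alc < gamma_w:
        raise DomainError("need gamma_alc < gamma_w")
    x = np.linspace(0.0, 1.0, n_points)
    gamma = _gamma_shape(x, gamma_w, gamma_alc, shape, ell, beta)
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    gamma_obs = gamma if rng is None else np.clip(
        gamma + rng.normal(0.0, noise_sd, size=gamma.shape), 1e-6, None
    )
    table = pd.DataFrame({"x": x, "gamma_mN_per_m": gamma_obs})
    lines = {}
    for theta_w in theta_w_list:
        line = zisman_from_endpoints(gamma_w, theta_w, gamma_alc)
        adh = line.c0 + line.c1 * gamma
        if rng is not None:
            adh = adh + rng.normal(0.0, noise_sd, size=adh.shape)
        key = f"{theta_w:g}"
        table[f"adh_tension_{key}"] = adh
        table[f"cos_theta_{key}"] = np.clip(adh / gamma, -1.0, 1.0)
        lines[key] = {"c0": line.c0, "c1": line.c1}
    truth = {
        "gamma_w": gamma_w, "gamma_alc": gamma_alc, "shape": shape,
        "ell": ell, "beta": beta, "noise_sd": noise_sd, "seed": seed,
        "zisman_lines": lines,
    }
    return table, truth
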