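"""Generalized plate-model leaf optics (PROSPECT-family forward model).

The leaf is represented as ``n`` identical absorbing plates with rough
air/cell-wall interfaces. Per wavelength the model needs (i) the bulk
absorption ``k`` obtained by summing specific absorption coefficients
weighted by constituent contents, (ii) the isotropic plate
transmissivity ``theta(k) = (1-k) e^-k + k^2 E1(k)``, and (iii) average
Fresnel interface transmissivities ``tav(alpha, n_refr)`` for the
incidence cone (40 deg for the upper, illuminated interface; 90 deg,
i.e. isotropic, for internal interfaces). Single-plate reflectance and
transmittance follow from the interface algebra; the stack of ``n``
(possibly non-integer) plates is solved with the Stokes recurrences in
their continuous form.

The xanthophyll-cycle extension represents carotenoid absorption as a
convex combination of a violaxanthin-dominated and a zeaxanthin-
dominated end-member spectrum, weighted by the de-epoxidation fraction
``cx`` — so ``cx`` is directly the (Z+A)/(Z+A+V) pool fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import exp1

from .types import GridMismatchError, LeafBiophysics, LeafSpectrum, SpectralGrid

__all__ = [
    "AbsorptionLibrary",
    "carotenoid_absorption",
    "total_absorption",
    "plate_transmissivity",
    "fresnel_average_transmissivity",
    "forward_model",
]


@dataclass
class AbsorptionLibrary:
    """Specific absorption coefficients and refractive index on a grid.

    ``k_car_v`` / ``k_car_z`` are the two carotenoid end members
    (violaxanthin- vs zeaxanthin-dominated pools); all coefficients are
    per unit content per plate. The library is pluggable: the packaged
    default is the synthetic one built by
    :func:`leafspec.synthetic.build_synthetic_library`, and any
    user-supplied coefficient table with the same columns (e.g. a
    canonical plate-model calibration) can be loaded through
    :func:`leafspec.io.read_library`.
    """

    grid: SpectralGrid
    n_refr: np.ndarray
    k_ab: np.ndarray
    k_car_v: np.ndarray
    k_car_z: np.ndarray
    k_anth: np.ndarray
    k_brown: np.ndarray
    k_w: np.ndarray
    k_m: np.ndarray
    # cached interface transmissivities (depend only on n_refr)
    _tav40: np.ndarray = field(init=False, repr=False)
    _tav90: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = len(self.grid)
        for name in ("n_refr", "k_ab", "k_car_v", "k_car_z", "k_anth",
                     "k_brown", "k_w", "k_m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise GridMismatchError(f"{name} does not conform to the grid")
            setattr(self, name, arr)
        if np.any(self.n_refr < 1):
            raise ValueError("refractive index must be >= 1")
        for name in ("k_ab", "k_car_v", "k_car_z", "k_anth", "k_brown", "k_w", "k_m"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} has negative coefficients")
        self._tav40 = fresnel_average_transmissivity(40.0, self.n_refr)
        self._tav90 = fresnel_average_transmissivity(90.0, self.n_refr)


def carotenoid_absorption(ccar: float, cx: float, lib: AbsorptionLibrary) -> np.ndarray:
    """Carotenoid absorption spectrum with xanthophyll-cycle mixing.

    Returns ``ccar * [(1 - cx) * K_car_V + cx * K_car_Z]``.
    """
    if ccar < 0:
        raise ValueError("ccar must be non-negative")
    if not 0.0 <= cx <= 1.0:
        raise ValueError("cx must lie in [0, 1]")
    return ccar * ((1.0 - cx) * lib.k_car_v + cx * lib.k_car_z)


def total_absorption(p: LeafBiophysics, lib: AbsorptionLibrary) -> np.ndarray:
    """Per-plate bulk absorption k(lambda): constituent sum divided by n."""
    k = (
        p.cab * lib.k_ab
        + carotenoid_absorption(p.ccar, p.cx, lib)
        + p.canth * lib.k_anth
        + p.cbrown * lib.k_brown
        + p.cw * lib.k_w
        + p.cm * lib.k_m
    ) / p.n
    return k


def plate_transmissivity(k):
    """Transmissivity of one plate under isotropic illumination.

    theta(k) = (1 - k) e^-k + k^2 E1(k), E1 the exponential integral.
    Evaluated directly in double precision; the subtraction loses only a
    few of the 16 digits over the physical range, and the result is
    clamped to [0, 1] to absorb rounding at the extremes. theta(0) = 1
    exactly, theta is strictly decreasing, and theta -> 0 as k -> inf.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("absorption k must be non-negative")
    with np.errstate(over="ignore", invalid="ignore"):
        # exp1(0) = inf but k^2 * E1(k) -> 0; substitute 1 under the mask
        safe = np.where(k > 0, k, 1.0)
        theta = (1.0 - k) * np.exp(-k) + k * k * exp1(safe)
    theta = np.where(k > 0, theta, 1.0)
    return np.clip(theta, 0.0, 1.0)


def fresnel_average_transmissivity(alpha: float, n):
    """Average Fresnel transmissivity over an incidence cone.

    Transmissivity of a plane dielectric interface of refractive index
    ``n``, averaged (radiance-weighted) over incidence angles from 0 to
    ``alpha`` degrees, unpolarized light. Uses the closed-form solution
    of the angular integral (Stern's formula as used throughout the
    plate-model literature). Equals 1 for n = 1 and decreases with n.
    """
    if not 0.0 < alpha <= 90.0:
        raise ValueError("alpha must lie in (0, 90] degrees")
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("refractive index must be >= 1")
    scalar = n.ndim == 0
    n = np.atleast_1d(n)
    out = np.ones_like(n)
    m = n > 1.0 + 1e-12
    if np.any(m):
        nn = n[m]
        sa = np.sin(np.deg2rad(alpha))
        n2 = nn ** 2
        npl = n2 + 1.0
        nm = n2 - 1.0
        a = (nn + 1.0) ** 2 / 2.0
        kk = -(nm ** 2) / 4.0
        b2 = sa ** 2 - npl / 2.0
        b1 = np.sqrt(np.clip(b2 ** 2 + kk, 0.0, None))  # exactly 0 at alpha=90
        b = b1 - b2
        b3, a3 = b ** 3, a ** 3
        ts = (kk ** 2 / (6.0 * b3) + kk / b - b / 2.0) - (
            kk ** 2 / (6.0 * a3) + kk / a - a / 2.0
        )
        tp1 = -2.0 * n2 * (b - a) / npl ** 2
        tp2 = -2.0 * n2 * npl * np.log(b / a) / nm ** 2
        tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
        tp4 = (
            16.0 * n2 ** 2 * (n2 ** 2 + 1.0)
            * np.log((2.0 * npl * b - nm ** 2) / (2.0 * npl * a - nm ** 2))
            / (npl ** 3 * nm ** 2)
        )
        tp5 = (
            16.0 * n2 ** 3
            * (1.0 / (2.0 * npl * b - nm ** 2) - 1.0 / (2.0 * npl * a - nm ** 2))
            / npl ** 3
        )
        out[m] = (ts + tp1 + tp2 + tp3 + tp4 + tp5) / (2.0 * sa ** 2)
    return float(out[0]) if scalar else out


def forward_model(p: LeafBiophysics, lib: AbsorptionLibrary) -> LeafSpectrum:
    """Reflectance and transmittance of a leaf with parameters ``p``.

    Single-plate r, t from the interface algebra with tav(40, n) at the
    illuminated surface and tav(90, n) internally; the remaining
    ``n - 1`` plates via the continuous Stokes solution; the two
    subsystems combined by the adding equations.
    """
    k = total_absorption(p, lib)
    tau = plate_transmissivity(k)
    nr = lib.n_refr
    talf = lib._tav40
    ralf = 1.0 - talf
    t12 = lib._tav90
    r12 = 1.0 - t12
    t21 = t12 / nr ** 2
    r21 = 1.0 - t21

    # top (illuminated) plate seen from above, and the same plate under
    # diffuse illumination from below/inside
    denom = 1.0 - (r21 * tau) ** 2
    Ta = talf * tau * t21 / denom
    Ra = ralf + r21 * tau * Ta
    t = t12 * tau * t21 / denom
    r = r12 + r21 * tau * t

    # Stokes continuation for the remaining n-1 plates
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        D = np.sqrt(np.clip(
            (1.0 + r + t) * (1.0 + r - t) * (1.0 - r + t) * (1.0 - r - t),
            0.0, None,
        ))
        rq, tq = r ** 2, t ** 2
        a = (1.0 + rq - tq + D) / (2.0 * r)
        b = (1.0 - rq + tq + D) / (2.0 * t)
        bNm1 = b ** (p.n - 1.0)
        bN2 = bNm1 ** 2
        a2 = a ** 2
        den2 = a2 * bN2 - 1.0
        Rsub = a * (bN2 - 1.0) / den2
        Tsub = bNm1 * (a2 - 1.0) / den2

    # conservative-scattering limit (no absorption: r + t -> 1)
    j = tau >= 1.0 - 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        Tj = t / (t + (1.0 - t) * (p.n - 1.0))
    Tsub = np.where(j, Tj, Tsub)
    Rsub = np.where(j, 1.0 - Tj, Rsub)
    # transparent-interface limit (r -> 0): plates only attenuate
    small = (r < 1e-12) & ~j
    if np.any(small):
        Tsub = np.where(small, t ** (p.n - 1.0), Tsub)
        Rsub = np.where(small, 0.0, Rsub)

    den3 = 1.0 - Rsub * r
    tran = Ta * Tsub / den3
    refl = Ra + Ta * Rsub * t / den3

    if not (np.all(np.isfinite(refl)) and np.all(np.isfinite(tran))):
        raise FloatingPointError(
            "non-finite spectrum: pathological parameters or coefficients"
        )
    refl = np.clip(refl, 0.0, None)
    tran = np.clip(tran, 0.0, None)
    s = refl + tran
    over = s > 1.0  # floating-point overshoot of the passive bound only
    if np.any(over):
        refl = np.where(over, refl / s, refl)
        tran = np.where(over, tran / s, tran)
    return LeafSpectrum(lib.grid, refl, tran)
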