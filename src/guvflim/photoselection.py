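"""Photoselection model for dipoles on a cone about the membrane normal.

A giant unilamellar vesicle imaged at its equator appears as a ring in the
ZOY image plane; the excitation laser is polarized along Y and photons are
collected along X through analyzers parallel (Y) and perpendicular (Z) to
the excitation polarization.  Membrane-bound chromophores sit at a fixed
polar angle ``nu`` to the local membrane normal with a uniform azimuth, so
the probability of excitation at each ring position is an analytic second
moment of the dipole distribution.  Comparing the lifetime-weighted
fluorescence pooled from the two membrane fragments perpendicular to Z and
to Y inverts to the mean orientation angle ``nu``.

Angles are degrees at every public interface and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MAGIC_ANGLE_DEG",
    "OrientationAngle",
    "EmissionDipoleOffset",
    "SectorObservation",
    "OrientationResult",
    "QuadratureError",
    "absorption_sector_Z",
    "absorption_sector_Y",
    "ring_excitation_weight",
    "aperture_averaged_weight",
    "predicted_sector_ratio",
    "invert_orientation",
    "invert_observation",
    "beta_from_fundamental_anisotropy",
    "polarized_emission_fractions",
    "emission_anisotropy",
]

#: Orientation angle (deg) at which cos^2(nu) = 1/3 and the ring is uniform.
MAGIC_ANGLE_DEG = math.degrees(math.acos(math.sqrt(1.0 / 3.0)))


class QuadratureError(RuntimeError):
    """Azimuthal quadrature failed to reach the requested tolerance."""

    def __init__(self, message: str, achieved_tol: float):
        super().__init__(f"{message} (achieved tolerance {achieved_tol:.3e})")
        self.achieved_tol = achieved_tol


@dataclass(frozen=True)
class OrientationAngle:
    """Polar angle between the transition dipole and the membrane normal.

    The membrane azimuth is assumed uniform (the normal is a symmetry axis),
    so only ``nu`` survives averaging.  ``nu`` is reported in [0, 90] deg;
    the cone symmetry makes ``nu`` and ``180 - nu`` indistinguishable.
    """

    nu_deg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.nu_deg <= 90.0):
            raise ValueError(
                f"orientation angle must lie in [0, 90] deg, got {self.nu_deg}"
            )

    @property
    def nu_rad(self) -> float:
        return math.radians(self.nu_deg)

    @property
    def cos2nu(self) -> float:
        """cos^2(nu), the order parameter entering the absorption factors."""
        return math.cos(self.nu_rad) ** 2

    @classmethod
    def from_cos2nu(cls, cos2nu: float) -> "OrientationAngle":
        if not (0.0 <= cos2nu <= 1.0):
            raise ValueError(f"cos^2(nu) must lie in [0, 1], got {cos2nu}")
        return cls(math.degrees(math.acos(math.sqrt(cos2nu))))


@dataclass(frozen=True)
class EmissionDipoleOffset:
    """Angle beta between absorption and emission transition dipoles.

    Related to the fundamental anisotropy by r0 = (3 cos^2(beta) - 1) / 5.
    """

    beta_deg: float
    r0: float

    def __post_init__(self) -> None:
        if not (-0.2 <= self.r0 <= 0.4):
            raise ValueError(f"non-physical fundamental anisotropy: {self.r0}")
        if not (0.0 <= self.beta_deg <= 90.0):
            raise ValueError(f"beta must lie in [0, 90] deg, got {self.beta_deg}")


@dataclass(frozen=True)
class SectorObservation:
    """Pooled, background-corrected sector measurements for one vesicle.

    ``F_Z``/``F_Y`` are total fluorescence counts (F_par + 2*G*F_perp summed
    over both symmetric sectors) for the membrane fragments perpendicular to
    the Z and Y axes; ``tau_*_ns`` are the amplitude-averaged lifetimes of the
    same pooled fragments.  The proportionality coefficient between absorbed
    quanta and counts cancels in the ratio and is not stored.
    """

    F_Z: float
    F_Y: float
    tau_Z_ns: float
    tau_Y_ns: float
    aperture_deg: float

    def __post_init__(self) -> None:
        if self.F_Z < 0 or self.F_Y < 0:
            raise ValueError("sector fluorescence must be non-negative")
        if self.tau_Z_ns <= 0 or self.tau_Y_ns <= 0:
            raise ValueError("sector lifetimes must be positive")
        if not (0.0 < self.aperture_deg <= 360.0):
            raise ValueError(f"aperture must lie in (0, 360] deg, got {self.aperture_deg}")

    @property
    def ratio_R(self) -> float:
        return self.F_Z / self.F_Y

    @property
    def lifetime_ratio_T(self) -> float:
        return self.tau_Z_ns / self.tau_Y_ns


@dataclass(frozen=True)
class OrientationResult:
    """Recovered mean dipole orientation and the observables behind it."""

    nu_deg: float
    cos2nu: float
    ratio_R: float
    lifetime_ratio_T: float
    sigma_nu_deg: float


def absorption_sector_Z(orient: OrientationAngle) -> float:
    """Relative light absorption in the membrane fragment spanned by Z.

    With the excitation field along Y and the local normal along Z, the
    azimuth average replaces sin^2 of the dipole azimuth by 1/2, giving
    A_Z = (1 - cos^2 nu) / 2.
    """
    return 0.5 * (1.0 - orient.cos2nu)


def absorption_sector_Y(orient: OrientationAngle) -> float:
    """Relative light absorption in the membrane fragment spanned by Y.

    The local normal is parallel to the excitation field, so A_Y = cos^2 nu.
    ``A_Y + 2 A_Z = 1`` for every orientation.
    """
    return orient.cos2nu


def ring_excitation_weight(orient: OrientationAngle, psi_deg) -> np.ndarray | float:
    """Excitation probability at ring position ``psi`` (deg, from the Y axis).

    Continuous generalization of the two sector absorption factors:
    ``cos^2(nu) cos^2(psi) + 0.5 sin^2(nu) sin^2(psi)``; reduces to
    :func:`absorption_sector_Y` at psi = 0 and :func:`absorption_sector_Z`
    at psi = 90.  At the magic angle the ring is uniform.
    """
    psi = np.radians(np.asarray(psi_deg, dtype=float))
    c2 = orient.cos2nu
    w = c2 * np.cos(psi) ** 2 + 0.5 * (1.0 - c2) * np.sin(psi) ** 2
    return float(w) if np.isscalar(psi_deg) else w


def aperture_averaged_weight(orient: OrientationAngle, axis: str, aperture_deg: float) -> float:
    """Mean excitation weight over a sector of full aperture about one axis.

    Analytic average of :func:`ring_excitation_weight` over
    ``psi in [axis - aperture/2, axis + aperture/2]``; the curvature of the
    ring makes this differ slightly from the point value at the axis, which
    is the dominant systematic of the sector-ratio method.
    """
    if not (0.0 < aperture_deg <= 360.0):
        raise ValueError(f"aperture must lie in (0, 360] deg, got {aperture_deg}")
    a = math.radians(aperture_deg / 2.0)
    sc = math.sin(a) * math.cos(a)
    c2 = orient.cos2nu
    s2 = 1.0 - c2
    if axis.upper() == "Y":
        return (c2 * (a + sc) + 0.5 * s2 * (a - sc)) / (2.0 * a)
    if axis.upper() == "Z":
        return (c2 * (a - sc) + 0.5 * s2 * (a + sc)) / (2.0 * a)
    raise ValueError(f"axis must be 'Z' or 'Y', got {axis!r}")


def predicted_sector_ratio(
    orient: OrientationAngle, tau_Z_ns: float = 1.0, tau_Y_ns: float = 1.0
) -> float:
    """Forward model for the sector fluorescence ratio R = F_Z / F_Y.

    Fluorescence is proportional to absorbed quanta times the quantum yield,
    the latter proxied by the amplitude-averaged lifetime of each fragment:
    ``R = (tau_Z / tau_Y) * (1 - cos^2 nu) / (2 cos^2 nu)``.

    Raises ``ValueError`` for nu = 90 deg where the ratio is unbounded.
    """
    if tau_Z_ns <= 0 or tau_Y_ns <= 0:
        raise ValueError("lifetimes must be positive")
    c2 = orient.cos2nu
    if c2 < 1e-24:  # nu = 90 deg up to floating-point rounding of cos^2
        raise ValueError("nu = 90 deg: in-plane dipoles give an unbounded sector ratio")
    return (tau_Z_ns / tau_Y_ns) * (1.0 - c2) / (2.0 * c2)


def invert_orientation(
    ratio_R: float,
    tau_Z_ns: float = 1.0,
    tau_Y_ns: float = 1.0,
    *,
    F_Z: float | None = None,
    F_Y: float | None = None,
) -> OrientationResult:
    """Invert a measured sector ratio to the mean dipole orientation.

    With ``T = tau_Z / tau_Y``: ``cos^2 nu = T / (2 R + T)`` and
    ``nu = arccos(sqrt(cos^2 nu))``.  The round trip with
    :func:`predicted_sector_ratio` is the identity.

    If the raw pooled counts ``F_Z``/``F_Y`` are supplied, a first-order
    delta-method propagation of their Poisson variance yields
    ``sigma_nu_deg`` (uncertainty of ``T`` is neglected; it is far below the
    counting noise for the photon budgets used here).
    """
    if ratio_R <= 0:
        raise ValueError(f"non-physical sector ratio: {ratio_R}")
    if tau_Z_ns <= 0 or tau_Y_ns <= 0:
        raise ValueError("lifetimes must be positive")
    T = tau_Z_ns / tau_Y_ns
    cos2 = T / (2.0 * ratio_R + T)
    nu_rad = math.acos(math.sqrt(cos2))
    sigma = math.nan
    if F_Z is not None and F_Y is not None and F_Z > 0 and F_Y > 0:
        var_R = ratio_R**2 * (1.0 / F_Z + 1.0 / F_Y)
        dc2_dR = -2.0 * T / (2.0 * ratio_R + T) ** 2
        # d(nu)/d(cos2) diverges at nu -> 0 or 90; guard the endpoints
        denom = 2.0 * math.sqrt(max(cos2 * (1.0 - cos2), 1e-300))
        dnu_dR = abs(dc2_dR) / denom
        sigma = math.degrees(dnu_dR * math.sqrt(var_R))
    return OrientationResult(
        nu_deg=math.degrees(nu_rad),
        cos2nu=cos2,
        ratio_R=ratio_R,
        lifetime_ratio_T=T,
        sigma_nu_deg=sigma,
    )


def invert_observation(obs: SectorObservation) -> OrientationResult:
    """Orientation inversion straight from a :class:`SectorObservation`."""
    return invert_orientation(
        obs.ratio_R, obs.tau_Z_ns, obs.tau_Y_ns, F_Z=obs.F_Z, F_Y=obs.F_Y
    )


def beta_from_fundamental_anisotropy(r0: float) -> EmissionDipoleOffset:
    """Angle between absorption and emission dipoles from r0.

    Inverts ``r0 = (3 cos^2 beta - 1) / 5``; r0 = 0.4 means collinear
    dipoles, r0 = -0.2 perpendicular ones.
    """
    if not (-0.2 <= r0 <= 0.4):
        raise ValueError(f"non-physical fundamental anisotropy: {r0}")
    cos2b = (5.0 * r0 + 1.0) / 3.0
    beta_deg = math.degrees(math.acos(math.sqrt(min(max(cos2b, 0.0), 1.0))))
    return EmissionDipoleOffset(beta_deg=beta_deg, r0=r0)


# ---------------------------------------------------------------------------
# Polarized emission fractions
#
# Geometry: local membrane normal n(psi) = (0, cos psi, sin psi) in lab
# coordinates (X = optical axis, Y = excitation polarization, Z = the
# orthogonal image axis).  The dipole sits on a cone of polar angle nu about
# n with uniform azimuth alpha:
#     mu = cos(nu) n + sin(nu) (cos(alpha) x_hat + sin(alpha) v_hat),
#     v_hat = n x x_hat = (0, sin psi, -cos psi).
# Excitation probability is (mu . Y)^2; emission through an analyzer p is
# (mu_em . p)^2 for detection along X.  When the emission dipole lies on a
# cone of half-angle beta about mu, the average over the cone azimuth is the
# exact closed form  cos^2(beta) (mu.p)^2 + 0.5 sin^2(beta) (1 - (mu.p)^2).
# ---------------------------------------------------------------------------


def _fractions_on_grid(
    cos_nu: np.ndarray,
    sin_nu: np.ndarray,
    psi_rad: np.ndarray,
    beta_rad: float,
    n_azimuth: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuth-averaged (f_par, f_perp) on a uniform midpoint grid.

    ``cos_nu``/``sin_nu`` broadcast against ``psi_rad``; the result has the
    broadcast shape.  The integrands are trigonometric polynomials of low
    degree in alpha, so the uniform grid converges spectrally.
    """
    alpha = (np.arange(n_azimuth) + 0.5) * (2.0 * math.pi / n_azimuth)
    sa = np.sin(alpha)
    cpsi, spsi = np.cos(psi_rad), np.sin(psi_rad)

    # broadcast: [..., n_azimuth]
    def bx(v):
        return np.asarray(v, dtype=float)[..., None]

    # mu_x = sin(nu) cos(alpha) never enters: both analyzers lie in the YZ plane
    mu_y = bx(cos_nu * cpsi) + bx(sin_nu * spsi) * sa
    mu_z = bx(cos_nu * spsi) - bx(sin_nu * cpsi) * sa

    w_exc = mu_y**2
    c2b, s2b = math.cos(beta_rad) ** 2, math.sin(beta_rad) ** 2
    em_par = c2b * mu_y**2 + 0.5 * s2b * (1.0 - mu_y**2)
    em_perp = c2b * mu_z**2 + 0.5 * s2b * (1.0 - mu_z**2)
    f_par = np.mean(w_exc * em_par, axis=-1)
    f_perp = np.mean(w_exc * em_perp, axis=-1)
    return f_par, f_perp


def polarized_emission_fractions(
    orient: OrientationAngle | None,
    psi_deg,
    beta_deg: float = 0.0,
    rtol: float = 1e-6,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Relative intensities in the parallel and perpendicular channels.

    Returns the azimuth-averaged ``<(mu.Y)^2 (mu_em.p)^2>`` for analyzers
    ``p = Y`` (parallel) and ``p = Z`` (perpendicular) at ring position
    ``psi`` (deg from the Y axis).  ``orient=None`` selects an ensemble
    uniform on the sphere (orientational disorder), for which the classic
    photoselection anisotropy r = 0.4 is recovered at beta = 0.

    The membrane azimuth integral is evaluated on a doubling midpoint grid
    until successive refinements agree to ``rtol``; failure raises
    :class:`QuadratureError` carrying the achieved tolerance.
    """
    if beta_deg < 0:
        raise ValueError("beta must be non-negative")
    psi = np.radians(np.asarray(psi_deg, dtype=float))
    beta = math.radians(beta_deg)

    psi_flat = psi.reshape(-1)
    if orient is None:
        # uniform sphere: cos(nu') ~ U(0, 1) by symmetry of (mu.p)^2 in mu
        nodes, weights = np.polynomial.legendre.leggauss(64)
        u = 0.5 * (nodes + 1.0)  # cos nu'
        wq = 0.5 * weights
        cos_nu = np.repeat(u[:, None], psi_flat.size, axis=1)
        sin_nu = np.sqrt(1.0 - cos_nu**2)
        psi_b = np.broadcast_to(psi_flat, cos_nu.shape)
    else:
        cos_nu = np.full(psi_flat.shape, math.cos(orient.nu_rad))
        sin_nu = np.full_like(cos_nu, math.sin(orient.nu_rad))
        psi_b = psi_flat

    prev = None
    n = 64
    achieved = math.inf
    for _ in range(6):
        f_par, f_perp = _fractions_on_grid(cos_nu, sin_nu, psi_b, beta, n)
        if orient is None:
            f_par = np.tensordot(wq, f_par, axes=(0, 0))
            f_perp = np.tensordot(wq, f_perp, axes=(0, 0))
        cur = np.stack([np.atleast_1d(f_par), np.atleast_1d(f_perp)])
        if prev is not None:
            scale = max(float(np.max(np.abs(cur))), 1e-12)
            achieved = float(np.max(np.abs(cur - prev))) / scale
            if achieved <= rtol:
                prev = cur
                break
        prev = cur
        n *= 2
    else:
        raise QuadratureError("azimuthal quadrature did not converge", achieved)

    f_par = prev[0].reshape(psi.shape)
    f_perp = prev[1].reshape(psi.shape)
    if np.isscalar(psi_deg):
        return float(f_par), float(f_perp)
    return f_par, f_perp


def emission_anisotropy(f_par, f_perp) -> np.ndarray | float:
    """Anisotropy r = (f_par - f_perp) / (f_par + 2 f_perp) of channel fractions."""
    f_par = np.asarray(f_par, dtype=float)
    f_perp = np.asarray(f_perp, dtype=float)
    denom = f_par + 2.0 * f_perp
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (f_par - f_perp) / denom, np.nan)
    return float(r) if r.ndim == 0 else r
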