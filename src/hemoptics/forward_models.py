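"""Analytical photon-diffusion forward models for semi-infinite homogeneous tissue.

These are the physical models behind hybrid transcranial diffuse optics:

* time-resolved diffuse reflectance ``R(rho, t)`` for time-resolved
  near-infrared spectroscopy (TR-NIRS),
* the normalized field autocorrelation ``g1(tau)`` of the correlation
  diffusion equation for diffuse correlation spectroscopy (DCS),
* the Siegert relation linking ``g1`` to the measured intensity
  autocorrelation ``g2``,
* instrument-response-function (IRF) convolution of model photon
  distributions of time of flight (DTOFs).

All models use the extrapolated-boundary semi-infinite geometry with an
image source at depth ``z0 = 1/musp`` and a mirror source above the
extrapolated boundary at ``zb = 2*A*D``, where ``A`` depends on the
refractive-index mismatch through the effective reflection coefficient.
The diffusion coefficient is absorption-free, ``D = 1/(3*musp)``.

Units are fixed throughout the package: lengths in mm, DTOF times in ps,
correlation lags in s, optical coefficients in 1/mm, blood flow index
(BFi) in mm^2/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT_MM_PS",
    "OpticalProperties",
    "Geometry",
    "G2Curve",
    "DTOF",
    "effective_reflection_coefficient",
    "td_reflectance",
    "g1_semiinf",
    "g2_from_g1",
    "g1_from_g2",
    "convolve_irf",
    "wavenumber_in_medium",
]

#: Vacuum speed of light in mm/ps.
SPEED_OF_LIGHT_MM_PS = 0.299792458


class ValidationError(ValueError):
    """Raised when a domain object or argument violates its invariants."""


@dataclass(frozen=True)
class OpticalProperties:
    """Tissue optical properties at one wavelength.

    Parameters
    ----------
    mua : float
        Absorption coefficient, 1/mm.
    musp : float
        Reduced scattering coefficient, 1/mm.
    n : float
        Tissue refractive index (default 1.4, the standard soft-tissue value).
    wavelength : float
        Wavelength in nm (metadata; not used by the diffusion models).
    """

    mua: float
    musp: float
    n: float = 1.4
    wavelength: float = 785.0

    def __post_init__(self) -> None:
        if not (self.mua > 0):
            raise ValidationError(f"mua must be > 0, got {self.mua}")
        if not (self.musp > 0):
            raise ValidationError(f"musp must be > 0, got {self.musp}")
        if self.n < 1:
            raise ValidationError(f"refractive index must be >= 1, got {self.n}")
        if self.musp / self.mua < 10:
            warnings.warn(
                "diffusion approximation questionable: musp/mua = "
                f"{self.musp / self.mua:.1f} < 10",
                stacklevel=2,
            )

    @property
    def v(self) -> float:
        """Speed of light in the medium, mm/ps."""
        return SPEED_OF_LIGHT_MM_PS / self.n

    @property
    def D(self) -> float:
        """Photon diffusion coefficient 1/(3*musp), mm (absorption-free)."""
        return 1.0 / (3.0 * self.musp)


def effective_reflection_coefficient(n: float) -> float:
    """Effective Fresnel reflection coefficient R_eff for a tissue/air boundary.

    Polynomial approximation in the internal relative refractive index
    (Groenhuis-style), accurate to ~1% for n in [1.0, 1.6].
    """
    if n < 1:
        raise ValidationError(f"refractive index must be >= 1, got {n}")
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


@dataclass(frozen=True)
class Geometry:
    """Source-detector geometry on a semi-infinite medium.

    ``z0`` and ``zb`` are the isotropic-source depth and extrapolated-boundary
    distance; when left at 0 they are derived from the optical properties at
    evaluation time (``z0 = 1/musp``, ``zb = 2*A*D`` with
    ``A = (1 + R_eff)/(1 - R_eff)``).
    """

    rho: float
    z0: float = 0.0
    zb: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rho > 0):
            raise ValidationError(f"source-detector separation must be > 0, got {self.rho}")
        if self.z0 < 0 or self.zb < 0:
            raise ValidationError("boundary parameters z0, zb must be >= 0")

    def boundary(self, op: OpticalProperties) -> tuple[float, float]:
        """Return ``(z0, zb)``, deriving unset values from ``op``."""
        z0 = self.z0 if self.z0 > 0 else 1.0 / op.musp
        if self.zb > 0:
            zb = self.zb
        else:
            reff = effective_reflection_coefficient(op.n)
            A = (1.0 + reff) / (1.0 - reff)
            zb = 2.0 * A * op.D
        return z0, zb


@dataclass
class G2Curve:
    """A measured (or simulated) normalized intensity autocorrelation curve.

    ``tau`` in seconds, strictly increasing; ``g2`` dimensionless; ``beta``
    the coherence factor in (0, 1]; ``count_rate`` in detected photons/s
    (drives the correlation-noise model).
    """

    tau: np.ndarray
    g2: np.ndarray
    beta: float = 0.5
    count_rate: float = 1e5

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.tau.shape != self.g2.shape:
            raise ValidationError("tau and g2 must have equal shapes")
        if self.tau.size and (np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0)):
            raise ValidationError("tau must be strictly increasing and > 0")
        if not (0 < self.beta <= 1):
            raise ValidationError(f"beta must be in (0, 1], got {self.beta}")


@dataclass
class DTOF:
    """A photon distribution of times of flight with its instrument response.

    ``t_bins`` are uniformly spaced bin centers in ps; ``counts`` and ``irf``
    are photon counts per bin on the same grid.
    """

    t_bins: np.ndarray
    counts: np.ndarray
    irf: np.ndarray
    wavelength: float = 785.0

    def __post_init__(self) -> None:
        self.t_bins = np.asarray(self.t_bins, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.irf = np.asarray(self.irf, dtype=float)
        if not (len(self.t_bins) == len(self.counts) == len(self.irf)):
            raise ValidationError("t_bins, counts and irf must have equal lengths")
        if np.any(self.counts < 0) or np.any(self.irf < 0):
            raise ValidationError("counts and irf must be non-negative")
        if self.irf.sum() <= 0:
            raise ValidationError("irf must have positive total")
        dt = np.diff(self.t_bins)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValidationError("t_bins must be uniformly spaced")

    @property
    def bin_width(self) -> float:
        return float(self.t_bins[1] - self.t_bins[0])


def td_reflectance(
    op: OpticalProperties, geom: Geometry, t: np.ndarray
) -> np.ndarray:
    """Time-resolved diffuse reflectance R(rho, t) of a semi-infinite medium.

    Image-source extrapolated-boundary solution evaluated as the normal
    photon-flux (Fick) reflectance:

    ``R(rho,t) = (4 pi D v)^{-3/2} t^{-5/2} / 2 * exp(-mua v t - rho^2/(4 D v t))
    * [z0 exp(-z0^2/(4Dvt)) + (z0+2zb) exp(-(z0+2zb)^2/(4Dvt))]``

    Parameters
    ----------
    t : array_like
        Times in ps, all strictly positive.

    Returns
    -------
    ndarray
        Reflectance in 1/mm^2/ps.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("td_reflectance requires all t > 0")
    D, v = op.D, op.v
    z0, zb = geom.boundary(op)
    zpos, zneg = z0, z0 + 2.0 * zb
    four_dvt = 4.0 * D * v * t
    pref = 0.5 * (np.pi * four_dvt) ** -1.5 * t**-1.0
    # note: (4 pi D v)^{-3/2} t^{-5/2} == (pi * 4 D v t)^{-3/2} / t
    decay = np.exp(-op.mua * v * t - geom.rho**2 / four_dvt)
    dipole = zpos * np.exp(-(zpos**2) / four_dvt) + zneg * np.exp(-(zneg**2) / four_dvt)
    return pref * decay * dipole


def wavenumber_in_medium(wavelength_nm: float, n: float = 1.4) -> float:
    """Optical wavenumber k0 = 2 pi n / lambda in 1/mm."""
    return 2.0 * np.pi * n / (wavelength_nm * 1e-6)


def g1_semiinf(
    op: OpticalProperties,
    geom: Geometry,
    bfi: float,
    k0: float,
    tau: np.ndarray,
) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) for semi-infinite tissue.

    Solves the correlation diffusion equation with the diffusive-flow model
    of scatterer motion, mean-square displacement ``<dr^2(tau)> = 6 BFi tau``,
    giving the decaying effective attenuation
    ``K(tau)^2 = 3 musp mua + 6 musp^2 k0^2 BFi tau``. The unnormalized
    solution is the image-source pair ``exp(-K r1)/r1 - exp(-K r2)/r2``;
    g1 is normalized to its tau -> 0 limit.

    Parameters
    ----------
    bfi : float
        Blood flow index in mm^2/s (>= 0).
    k0 : float
        Optical wavenumber in the medium, 1/mm.
    tau : array_like
        Correlation lags in s, strictly positive.
    """
    if bfi < 0:
        raise ValidationError(f"bfi must be >= 0, got {bfi}")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValidationError("tau must be > 0")
    z0, zb = geom.boundary(op)
    r1 = np.hypot(geom.rho, z0)
    r2 = np.hypot(geom.rho, z0 + 2.0 * zb)

    def unnorm(k: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-k * r1) / r1 - np.exp(-k * r2) / r2

    ksq0 = 3.0 * op.musp * op.mua
    k_tau = np.sqrt(ksq0 + 6.0 * op.musp**2 * k0**2 * bfi * tau)
    g1 = unnorm(k_tau) / unnorm(np.sqrt(ksq0))
    return np.clip(g1, 0.0, 1.0)


def g2_from_g1(g1: np.ndarray, beta: float) -> np.ndarray:
    """Siegert relation: g2 = 1 + beta * g1^2."""
    if not (0 < beta <= 1):
        raise ValidationError(f"beta must be in (0, 1], got {beta}")
    g1 = np.asarray(g1, dtype=float)
    return 1.0 + beta * g1**2


def g1_from_g2(g2: np.ndarray, beta: float) -> np.ndarray:
    """Inverse Siegert map sqrt(max(g2 - 1, 0)/beta)."""
    if not (0 < beta <= 1):
        raise ValidationError(f"beta must be in (0, 1], got {beta}")
    g2 = np.asarray(g2, dtype=float)
    return np.sqrt(np.clip(g2 - 1.0, 0.0, None) / beta)


def convolve_irf(model_dtof: np.ndarray, irf: np.ndarray, bin_width: float) -> np.ndarray:
    """Discrete convolution of a model DTOF with an IRF, truncated to the window.

    Output length equals input length; the total integral scales as
    ``sum(model) * sum(irf) * bin_width`` (up to truncation of the tail).
    """
    model_dtof = np.asarray(model_dtof, dtype=float)
    irf = np.asarray(irf, dtype=float)
    if model_dtof.shape != irf.shape:
        raise ValidationError("model and irf must have equal lengths")
    if irf.sum() <= 0:
        raise ValidationError("irf must have positive total")
    return np.convolve(model_dtof, irf)[: len(model_dtof)] * bin_width
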