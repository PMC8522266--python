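"""Inverse problems for hybrid diffuse optics.

Recovers absolute optical properties (mua, musp) from a measured DTOF and
its instrument response function, and the blood flow index BFi (with the
coherence factor beta) from a measured intensity autocorrelation curve, by
bounded nonlinear least squares against the analytical forward models.

Both fits use deterministic initialization (config defaults, no random
restarts) so results are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .forward_models import (
    DTOF,
    G2Curve,
    Geometry,
    OpticalProperties,
    ValidationError,
    convolve_irf,
    g1_semiinf,
    td_reflectance,
)

__all__ = [
    "DtofFitResult",
    "G2FitResult",
    "default_fit_window",
    "fit_dtof",
    "fit_g2",
]

# deterministic initial guesses (typical adult head values)
DEFAULT_MUA0 = 0.01  # 1/mm
DEFAULT_MUSP0 = 1.0  # 1/mm
DEFAULT_BFI0 = 1e-6  # mm^2/s
DEFAULT_BETA0 = 0.5


@dataclass(frozen=True)
class DtofFitResult:
    """Result of a TR-NIRS DTOF fit."""

    mua: float
    musp: float
    amplitude: float
    t_shift: float
    residual_norm: float
    converged: bool
    fit_window: tuple[int, int]


@dataclass(frozen=True)
class G2FitResult:
    """Result of a DCS g2 fit."""

    bfi: float
    beta: float
    residual_norm: float
    converged: bool


def default_fit_window(counts: np.ndarray, rise_frac: float = 0.5, tail_frac: float = 0.01) -> tuple[int, int]:
    """Fit window from 50% of peak on the rising edge to 1% of peak on the tail.

    Returns (lo, hi) bin indices, hi exclusive.
    """
    counts = np.asarray(counts, dtype=float)
    peak = counts.max()
    if peak <= 0:
        raise ValidationError("DTOF has no counts; cannot derive a fit window")
    ipk = int(np.argmax(counts))
    above = np.nonzero(counts[: ipk + 1] >= rise_frac * peak)[0]
    lo = int(above[0]) if above.size else 0
    below = np.nonzero(counts[ipk:] < tail_frac * peak)[0]
    hi = int(ipk + below[0]) if below.size else len(counts)
    if hi <= lo:
        raise ValidationError("degenerate fit window")
    return lo, hi


def _dtof_model(
    dtof: DTOF,
    geom: Geometry,
    mua: float,
    musp: float,
    t_shift: float,
    n: float,
) -> np.ndarray:
    """Unit-amplitude model: R(rho, t) convolved with the IRF, shifted by t_shift ps."""
    op = OpticalProperties(mua=mua, musp=musp, n=n, wavelength=dtof.wavelength)
    t = dtof.t_bins
    pos = t > 0
    refl = np.zeros_like(t)
    refl[pos] = td_reflectance(op, geom, t[pos])
    conv = convolve_irf(refl, dtof.irf, dtof.bin_width)
    if t_shift == 0.0:
        return conv
    return np.interp(t - t_shift, t, conv, left=0.0, right=0.0)


def fit_dtof(
    dtof: DTOF,
    geom: Geometry,
    init: OpticalProperties | None = None,
    window: tuple[int, int] | None = None,
    fit_shift: bool = True,
    max_shift: float = 200.0,
    max_nfev: int = 200,
) -> DtofFitResult:
    """Recover (mua, musp) from a DTOF by weighted nonlinear least squares.

    The model is the semi-infinite time-domain reflectance convolved with the
    measured IRF; free parameters are (mua, musp, t_shift), with the overall
    amplitude solved analytically at each iteration (it enters linearly).
    Weights are Poisson, ``1/sqrt(max(counts, 1))``. The fit window defaults
    to 50% of peak on the rising edge down to 1% of peak on the tail.

    Raises
    ------
    ValidationError
        If the window is empty or contains fewer than 1000 counts.
    """
    if window is None:
        window = default_fit_window(dtof.counts)
    lo, hi = window
    if not (0 <= lo < hi <= len(dtof.counts)):
        raise ValidationError(f"fit window {window} outside data range")
    y = dtof.counts[lo:hi]
    if y.sum() < 1000:
        raise ValidationError(
            f"only {y.sum():.0f} counts in fit window; need >= 1000 for a stable fit"
        )
    sigma = np.sqrt(np.maximum(y, 1.0))
    n = init.n if init is not None else 1.4
    mua0 = init.mua if init is not None else DEFAULT_MUA0
    musp0 = init.musp if init is not None else DEFAULT_MUSP0

    state = {"amp": 1.0}

    def residuals(theta: np.ndarray) -> np.ndarray:
        mua, musp, shift = theta
        m = _dtof_model(dtof, geom, mua, musp, shift, n)[lo:hi]
        mw = m / sigma
        yw = y / sigma
        denom = float(mw @ mw)
        amp = float(mw @ yw) / denom if denom > 0 else 0.0
        state["amp"] = amp
        return amp * mw - yw

    shift_bound = max_shift if fit_shift else 1e-9
    res = least_squares(
        residuals,
        x0=[mua0, musp0, 0.0],
        bounds=([1e-4, 0.05, -shift_bound], [0.5, 10.0, shift_bound]),
        x_scale=[0.01, 1.0, 50.0],
        max_nfev=max_nfev,
        method="trf",
    )
    mua, musp, shift = res.x
    converged = bool(res.success) and res.status > 0
    return DtofFitResult(
        mua=float(mua),
        musp=float(musp),
        amplitude=state["amp"],
        t_shift=float(shift),
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=converged,
        fit_window=(lo, hi),
    )


def _g2_fit_range(tau: np.ndarray, g2: np.ndarray, beta_guess: float, min_points: int = 20) -> slice:
    """Lags up to where g2 - 1 falls below 0.05 * beta (at least min_points)."""
    below = np.nonzero(g2 - 1.0 < 0.05 * beta_guess)[0]
    hi = int(below[0]) if below.size else len(tau)
    hi = max(hi, min(min_points, len(tau)))
    return slice(0, hi)


def fit_g2(
    curve: G2Curve,
    op: OpticalProperties,
    geom: Geometry,
    k0: float,
    max_nfev: int = 200,
) -> G2FitResult:
    """Recover (BFi, beta) from an intensity autocorrelation curve.

    Fits ``1 + beta * g1(tau; BFi)^2`` to the measured g2 jointly in
    (BFi, beta), restricted to lags where the correlation has not fully
    decayed (``g2 - 1 >= 0.05 * beta``). A flat curve (no decay) returns
    ``converged=False`` with BFi at the lower bound.
    """
    tau, g2 = curve.tau, curve.g2
    if tau.size < 20:
        raise ValidationError(f"need >= 20 lag points, got {tau.size}")
    beta_guess = float(np.clip(np.mean(g2[:3]) - 1.0, 1e-3, 1.0))
    sel = _g2_fit_range(tau, g2, beta_guess)
    t_fit, y_fit = tau[sel], g2[sel]

    def residuals(theta: np.ndarray) -> np.ndarray:
        bfi, beta = theta
        g1 = g1_semiinf(op, geom, bfi, k0, t_fit)
        return (1.0 + beta * g1**2) - y_fit

    res = least_squares(
        residuals,
        x0=[DEFAULT_BFI0, beta_guess],
        bounds=([0.0, 1e-3], [1e-2, 1.0]),
        x_scale=[1e-6, 0.1],
        max_nfev=max_nfev,
        method="trf",
    )
    bfi, beta = res.x
    decayed = (np.max(y_fit) - np.min(y_fit)) > 0.02 * beta_guess
    if not decayed:
        # no measurable decay: flow is unidentifiable, pin it at the bound
        bfi = 0.0
        beta = float(np.clip(np.mean(y_fit) - 1.0, 1e-3, 1.0))
    converged = bool(res.success) and decayed
    return G2FitResult(
        bfi=float(bfi),
        beta=float(beta),
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=converged,
    )
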