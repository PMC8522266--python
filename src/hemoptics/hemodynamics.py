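"""From fitted optics to physiology.

Multi-wavelength absorption is decomposed into oxy- and deoxy-hemoglobin
concentrations (after subtracting a fixed water contribution), giving tissue
oxygen saturation StO2 and total hemoglobin tHb. The DCS blood flow index is
interpreted relative to baseline (rCBF). Oxygen extraction fraction (OEF)
uses a venous-compartment reconstruction of SvO2 from StO2 and arterial
saturation, and relative CMRO2 follows from the Fick principle on relative
quantities:

    rCMRO2 = rCBF * (OEF_t / OEF_0) * (SaO2_t / SaO2_0)

Concentrations are in uM, extinction coefficients in 1/(mM*mm), absorption
in 1/mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward_models import ValidationError

__all__ = [
    "ExtinctionTable",
    "DEFAULT_EXTINCTION_TABLE",
    "HemoState",
    "chromophores_from_mua",
    "sto2_from_concentrations",
    "mua_from_concentrations",
    "relative_series",
    "oef",
    "rcmro2",
    "MODE_BY_PARAM",
]

LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class ExtinctionTable:
    """Hemoglobin extinction coefficients and water absorption per wavelength.

    ``eps_hbo``/``eps_hbr`` in 1/(mM*mm) (base-10), ``mua_water`` in 1/mm for
    pure water; ``water_fraction`` is the assumed tissue water volume
    fraction subtracted before the hemoglobin solve.
    """

    wavelengths: tuple[float, ...]
    eps_hbo: tuple[float, ...]
    eps_hbr: tuple[float, ...]
    mua_water: tuple[float, ...]
    water_fraction: float = 0.75

    def __post_init__(self) -> None:
        k = len(self.wavelengths)
        if k < 2:
            raise ValidationError("need >= 2 wavelengths")
        if not (len(self.eps_hbo) == len(self.eps_hbr) == len(self.mua_water) == k):
            raise ValidationError("extinction table columns must have equal lengths")

    def row(self, wavelength: float) -> tuple[float, float, float]:
        """(eps_hbo, eps_hbr, mua_water) at a tabulated wavelength."""
        for i, w in enumerate(self.wavelengths):
            if abs(w - wavelength) < 0.5:
                return self.eps_hbo[i], self.eps_hbr[i], self.mua_water[i]
        raise ValidationError(f"wavelength {wavelength} nm not in extinction table")

    @property
    def condition_number(self) -> float:
        m = np.column_stack([self.eps_hbo, self.eps_hbr])
        return float(np.linalg.cond(m))


# Molar extinction rounded from S. Prahl's compiled hemoglobin tabulation
# (cm^-1/M converted to 1/(mM*mm)); water absorption from Hale & Querry.
DEFAULT_EXTINCTION_TABLE = ExtinctionTable(
    wavelengths=(690.0, 785.0, 830.0),
    eps_hbo=(0.0276, 0.0730, 0.0974),
    eps_hbr=(0.2052, 0.1000, 0.0693),
    mua_water=(0.0005, 0.0023, 0.0029),
)


@dataclass
class HemoState:
    """Derived physiology at one time point."""

    hbo: float  # uM
    hbr: float  # uM
    rcbf: float = 1.0
    oef: float = float("nan")
    rcmro2: float = float("nan")
    sao2: float = float("nan")  # %

    @property
    def thb(self) -> float:
        return self.hbo + self.hbr

    @property
    def sto2(self) -> float:
        return 100.0 * self.hbo / self.thb


def mua_from_concentrations(
    hbo_um: float, hbr_um: float, table: ExtinctionTable = DEFAULT_EXTINCTION_TABLE
) -> dict[float, float]:
    """Forward map: absorption per wavelength from concentrations in uM."""
    out = {}
    for w, eo, er, mw in zip(table.wavelengths, table.eps_hbo, table.eps_hbr, table.mua_water):
        out[w] = LN10 * (eo * hbo_um + er * hbr_um) * 1e-3 + table.water_fraction * mw
    return out


def chromophores_from_mua(
    mua_by_wavelength: dict[float, float],
    table: ExtinctionTable = DEFAULT_EXTINCTION_TABLE,
) -> tuple[float, float]:
    """Solve mua(lambda) = ln10 [eps_HbO HbO + eps_HbR HbR] + water for (HbO, HbR) in uM.

    Exact for two wavelengths, least squares for more. Raises when the
    extinction sub-matrix is rank deficient, naming the wavelength set.
    """
    wavelengths = sorted(mua_by_wavelength)
    if len(wavelengths) < 2:
        raise ValidationError("need >= 2 wavelengths to separate HbO and HbR")
    rows, rhs = [], []
    for w in wavelengths:
        eo, er, mw = table.row(w)
        rows.append([LN10 * eo * 1e-3, LN10 * er * 1e-3])  # per uM
        rhs.append(mua_by_wavelength[w] - table.water_fraction * mw)
    m = np.asarray(rows)
    b = np.asarray(rhs)
    s = np.linalg.svd(m, compute_uv=False)
    if s[-1] / s[0] < 1e-10:
        raise ValidationError(
            f"extinction system rank deficient for wavelengths {wavelengths}"
        )
    sol, *_ = np.linalg.lstsq(m, b, rcond=None)
    return float(sol[0]), float(sol[1])


def sto2_from_concentrations(hbo_um: float, hbr_um: float) -> tuple[float, float]:
    """(StO2 %, tHb uM) from concentrations."""
    thb = hbo_um + hbr_um
    if thb <= 0:
        raise ValidationError("total hemoglobin must be positive")
    return 100.0 * hbo_um / thb, thb


def relative_series(
    x: np.ndarray,
    baseline: np.ndarray | slice,
    mode: str,
) -> np.ndarray:
    """Normalize a series to its baseline: ratio ('r') or difference ('delta').

    ``baseline`` selects the baseline samples (boolean mask, index array or
    slice); invalid (NaN) baseline samples are ignored.
    """
    x = np.asarray(x, dtype=float)
    base = x[baseline]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise ValidationError("baseline window contains no valid samples")
    m = base.mean()
    if mode == "r":
        if m == 0:
            raise ValidationError("zero baseline mean; ratio undefined")
        return x / m
    if mode in ("delta", "d"):
        return x - m
    raise ValidationError(f"unknown normalization mode {mode!r}")


def oef(
    sto2: float | np.ndarray,
    sao2: float | np.ndarray,
    gamma: float = 0.75,
) -> float | np.ndarray:
    """Oxygen extraction fraction from tissue and arterial saturations (%).

    The venous saturation is reconstructed assuming StO2 is a
    gamma-weighted venous/arterial mixture,
    ``SvO2 = (StO2 - (1 - gamma) SaO2) / gamma``, and
    ``OEF = (SaO2 - SvO2) / SaO2``. Values are clipped to [0, 1] with a
    warning when clipping occurs.
    """
    if not (0 < gamma <= 1):
        raise ValidationError(f"venous fraction gamma must be in (0, 1], got {gamma}")
    sto2 = np.asarray(sto2, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    if np.any(sao2 <= 0) or np.any(sao2 > 100):
        raise ValidationError("SaO2 must be in (0, 100] %")
    if np.any(sto2 > sao2 + 1e-9):
        warnings.warn("StO2 exceeds SaO2; OEF will be clipped", stacklevel=2)
    svo2 = (sto2 - (1.0 - gamma) * sao2) / gamma
    out = (sao2 - svo2) / sao2
    clipped = (out < 0) | (out > 1)
    if np.any(clipped):
        warnings.warn("OEF clipped to [0, 1]", stacklevel=2)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def rcmro2(
    rcbf: float | np.ndarray,
    oef_t: float | np.ndarray,
    oef_0: float,
    sao2_t: float | np.ndarray = 100.0,
    sao2_0: float = 100.0,
) -> float | np.ndarray:
    """Relative cerebral metabolic rate of oxygen via the Fick principle.

    ``rCMRO2 = rCBF * (OEF_t / OEF_0) * (SaO2_t / SaO2_0)``.
    """
    if oef_0 <= 0:
        raise ValidationError("baseline OEF must be > 0 (ratio undefined)")
    if sao2_0 <= 0:
        raise ValidationError("baseline SaO2 must be > 0")
    out = np.asarray(rcbf, dtype=float) * (np.asarray(oef_t, dtype=float) / oef_0) * (
        np.asarray(sao2_t, dtype=float) / sao2_0
    )
    return float(out) if out.ndim == 0 else out


#: Reporting mode per physiological parameter: ratio-to-baseline for flow and
#: metabolism, difference-from-baseline for everything else.
MODE_BY_PARAM: dict[str, str] = {
    "CBF": "r",
    "CMRO2": "r",
    "StO2": "delta",
    "tHb": "delta",
    "OEF": "delta",
    "MAP": "delta",
    "HR": "delta",
    "RR": "delta",
    "SpO2": "delta",
    "TcCO2": "delta",
    "EtCO2": "delta",
}
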