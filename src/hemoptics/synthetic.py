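"""Synthetic two-mask study generator.

Emulates the study protocol: per subject, a 10-min no-mask baseline epoch
followed by a 10-min mask epoch, for each of two mask types (FFP2 and
surgical), recorded bilaterally. Cerebral channels (CBF, StO2, tHb) carry a
shared per-subject mask effect plus independent per-hemisphere AR(1) noise;
systemic channels (MAP, HR, RR, SpO2, TcCO2, EtCO2) are common to both
hemispheres. The mask effect ramps in as a logistic sigmoid that starts
exactly at mask placement (t = 0), reaching half amplitude 60 s after
mask-on with a 20-s time constant, so the pre-mask baseline is clean and
the effect has plateaued well before the 3-min analysis mark.

Injected effect magnitudes in the ``paper_effects`` preset are the study's
reported population changes; between-subject effect SDs are chosen so the
13-subject confidence intervals resemble the reported CI widths (a
documented emulation choice, not ground truth).

Optionally, raw-level optical streams (intensity autocorrelation curves and
DTOFs) consistent with the underlying hemodynamics can be generated, so the
whole chain forward model -> fit -> physiology -> statistics closes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .forward_models import (
    DTOF,
    G2Curve,
    Geometry,
    OpticalProperties,
    ValidationError,
    convolve_irf,
    g1_semiinf,
    g2_from_g1,
    td_reflectance,
    wavenumber_in_medium,
)
from .hemodynamics import DEFAULT_EXTINCTION_TABLE, ExtinctionTable, mua_from_concentrations
from .pipeline import CEREBRAL_CHANNELS, SYSTEMIC_CHANNELS, EpochDesign, PhysioSeries

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "paper_effects",
    "null_effects",
    "lateralized_effects",
    "simulate_study",
    "simulate_raw_optics",
    "PRESETS",
]

MASKS = ("FFP2", "surgical")


@dataclass(frozen=True)
class EffectSpec:
    """A population-level mask effect on one parameter.

    ``population_mean`` is a ratio for r-mode parameters (e.g. 1.065 for a
    +6.5% CBF change) and an additive shift in channel units for
    difference-mode parameters. Per-subject effects are drawn
    ``N(population_mean, between_subject_sd)``.
    """

    parameter: str
    mask_type: str
    mode: str  # "r" or "delta"
    population_mean: float
    between_subject_sd: float
    transition_time_constant: float = 20.0

    def __post_init__(self) -> None:
        if self.mode == "r" and self.population_mean <= 0:
            raise ValidationError("ratio-mode effect mean must be > 0")
        if self.transition_time_constant < 0:
            raise ValidationError("transition time constant must be >= 0")
        if self.between_subject_sd < 0:
            raise ValidationError("between-subject sd must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for the generator.

    ``ar1_coeff`` and marginal ``sd`` are per channel (AR(1) with the given
    lag-1 autocorrelation and stationary standard deviation). The optical
    fields parameterize the raw-level noise: total DTOF counts per
    acquisition, DCS detected count rate (photons/s) and correlator
    averaging time (s).
    """

    ar1_coeff: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AR1))
    sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    dtof_total_counts: float = 1e6
    dcs_count_rate: float = 1e5
    dcs_t_avg: float = 1.0

    def __post_init__(self) -> None:
        for name, phi in self.ar1_coeff.items():
            if not (0 <= phi < 1):
                raise ValidationError(f"AR(1) coefficient for {name} must be in [0, 1)")
        if self.dtof_total_counts <= 0 or self.dcs_count_rate <= 0 or self.dcs_t_avg <= 0:
            raise ValidationError("optical noise parameters must be positive")


#: Marginal (stationary) noise SD per channel, in channel units.
DEFAULT_NOISE_SD = {
    "CBF": 2.0,  # a.u. (baseline ~50)
    "StO2": 0.8,  # %
    "tHb": 0.8,  # uM
    "MAP": 3.0,  # mmHg
    "HR": 2.0,  # bpm
    "RR": 1.5,  # breaths/min
    "SpO2": 0.3,  # %
    "TcCO2": 1.0,  # mmHg
    "EtCO2": 2.0,  # mmHg
}
DEFAULT_AR1 = {name: 0.9 for name in DEFAULT_NOISE_SD}

#: Per-subject baseline distributions (mean, between-subject SD).
BASELINE_DISTS = {
    "CBF": (50.0, 10.0),  # arbitrary perfusion units; analyzed as a ratio
    "StO2": (65.0, 3.0),  # %
    "tHb": (55.0, 6.0),  # uM
    "MAP": (85.0, 8.0),  # mmHg
    "HR": (70.0, 8.0),  # bpm
    "RR": (14.0, 2.0),  # breaths/min
    "SpO2": (98.0, 0.8),  # %
    "TcCO2": (40.0, 3.0),  # mmHg
    "EtCO2": (38.0, 3.0),  # mmHg
}


def _effect(parameter, mask, mode, mean, sd) -> EffectSpec:
    return EffectSpec(parameter, mask, mode, mean, sd)


def paper_effects() -> list[EffectSpec]:
    """The reported study effect magnitudes (both masks).

    Reported changes: CBF +6.5%/+6.2% (FFP2/surgical), StO2 +0.9% both,
    tHb +0.9 uM (FFP2; significant only there), MAP +4.1 mmHg and HR
    +2.0 bpm (surgical), RR -3.2 breaths/min (FFP2), no change in SpO2 or
    TcCO2, and a between-mask HR difference of 1.2 bpm. The arm the study
    found non-significant is given a smaller magnitude consistent with its
    interval (FFP2 HR +0.8 bpm makes the between-mask difference 1.2 bpm).
    EtCO2 carries a spurious positive shift emulating air trapped under the
    mask at the probe.
    """
    return [
        _effect("CBF", "FFP2", "r", 1.065, 0.065),
        _effect("CBF", "surgical", "r", 1.062, 0.062),
        _effect("StO2", "FFP2", "delta", 0.9, 1.25),
        _effect("StO2", "surgical", "delta", 0.9, 1.25),
        _effect("tHb", "FFP2", "delta", 0.9, 1.0),
        _effect("tHb", "surgical", "delta", 0.5, 1.0),
        _effect("MAP", "FFP2", "delta", 1.5, 5.9),
        _effect("MAP", "surgical", "delta", 4.1, 5.9),
        _effect("HR", "FFP2", "delta", 0.8, 1.75),
        _effect("HR", "surgical", "delta", 2.0, 1.75),
        _effect("RR", "FFP2", "delta", -3.2, 3.6),
        _effect("RR", "surgical", "delta", -1.5, 3.6),
        _effect("SpO2", "FFP2", "delta", 0.0, 0.4),
        _effect("SpO2", "surgical", "delta", 0.0, 0.4),
        _effect("TcCO2", "FFP2", "delta", 0.0, 1.5),
        _effect("TcCO2", "surgical", "delta", 0.0, 1.5),
        _effect("EtCO2", "FFP2", "delta", 6.0, 2.0),
        _effect("EtCO2", "surgical", "delta", 6.0, 2.0),
    ]


def null_effects() -> list[EffectSpec]:
    """Zero effect on every channel (for calibration runs)."""
    out = []
    for mask in MASKS:
        for name in BASELINE_DISTS:
            mode = "r" if name == "CBF" else "delta"
            out.append(
                EffectSpec(name, mask, mode, 1.0 if mode == "r" else 0.0, _null_sd(name))
            )
    return out


def _null_sd(name: str) -> float:
    sds = {
        "CBF": 0.065,
        "StO2": 1.25,
        "tHb": 1.0,
        "MAP": 5.9,
        "HR": 1.75,
        "RR": 3.6,
        "SpO2": 0.4,
        "TcCO2": 1.5,
        "EtCO2": 2.0,
    }
    return sds[name]


def lateralized_effects() -> list[EffectSpec]:
    """A left-hemisphere-only CBF effect (for hemisphere side-test checks)."""
    return [_effect("CBF", m, "r", 1.10, 0.03) for m in MASKS]


PRESETS = {
    "paper-effects": paper_effects,
    "null": null_effects,
    "lateralized": lateralized_effects,
}


def _sigmoid_onset(time: np.ndarray, t_half: float = 60.0, tau_c: float = 20.0) -> np.ndarray:
    """Logistic onset rescaled to be exactly 0 at t <= 0 and -> 1 as t -> inf."""
    if tau_c == 0:
        return (time >= t_half).astype(float)
    s = 1.0 / (1.0 + np.exp(-(time - t_half) / tau_c))
    s0 = 1.0 / (1.0 + np.exp(t_half / tau_c))
    out = (s - s0) / (1.0 - s0)
    out[time <= 0] = 0.0
    return out


def _ar1(rng: np.random.Generator, phi: float, sd: float, shape: tuple[int, ...]) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    burn = 100
    e = rng.normal(0.0, innov_sd, shape[:-1] + (shape[-1] + burn,))
    x = lfilter([1.0], [1.0, -phi], e, axis=-1)
    return x[..., burn:]


def simulate_study(
    n_subjects: int = 13,
    effects: list[EffectSpec] | None = None,
    noise: NoiseSpec | None = None,
    design: EpochDesign | None = None,
    seed: int = 0,
    fs_hz: float = 1.0,
    lateralized: bool = False,
) -> list[PhysioSeries]:
    """Generate the full synthetic study: both masks, both hemispheres.

    Per subject, baselines are drawn from documented population
    distributions, mask effects from the per-parameter effect
    distributions, and the time courses get stationary AR(1) measurement
    noise. The same per-subject cerebral effect drives both hemispheres
    (unless ``lateralized``, when cerebral effects apply to the left side
    only); systemic channels are identical across hemispheres. Fully
    reproducible from the seed.
    """
    effects = paper_effects() if effects is None else effects
    noise = noise or NoiseSpec()
    design = design or EpochDesign()
    rng = np.random.default_rng(seed)

    eff_by_key: dict[tuple[str, str], EffectSpec] = {}
    for e in effects:
        if e.parameter not in BASELINE_DISTS:
            raise ValidationError(f"effect on unknown parameter {e.parameter}")
        if e.mask_type not in MASKS:
            raise ValidationError(f"unknown mask type {e.mask_type}")
        eff_by_key[(e.parameter, e.mask_type)] = e

    t0 = design.baseline[0] - 300.0  # extra pre-baseline context
    time = np.arange(t0, design.analysis[1] + 1e-9, 1.0 / fs_hz)
    series: list[PhysioSeries] = []

    for i in range(n_subjects):
        subj = f"S{i + 1:02d}"
        baselines = {
            name: rng.normal(mu, sd) for name, (mu, sd) in BASELINE_DISTS.items()
        }
        baselines["SpO2"] = min(baselines["SpO2"], 100.0)
        baselines["StO2"] = float(np.clip(baselines["StO2"], 40.0, baselines["SpO2"] - 5.0))
        baselines["CBF"] = max(baselines["CBF"], 15.0)
        baselines["tHb"] = max(baselines["tHb"], 25.0)
        bfi_baseline = rng.normal(1.2e-6, 2e-7)

        for mask in MASKS:
            # per-subject effect draws (shared by hemispheres)
            subj_eff: dict[str, tuple[str, float, np.ndarray]] = {}
            for name in BASELINE_DISTS:
                spec = eff_by_key.get((name, mask))
                if spec is None:
                    mode = "r" if name == "CBF" else "delta"
                    subj_eff[name] = (mode, 1.0 if mode == "r" else 0.0, None)
                    continue
                val = rng.normal(spec.population_mean, spec.between_subject_sd)
                if spec.mode == "r":
                    val = max(val, 0.05)
                onset = _sigmoid_onset(time, 60.0, spec.transition_time_constant)
                subj_eff[name] = (spec.mode, val, onset)

            # trajectories without measurement noise
            clean: dict[str, np.ndarray] = {}
            for name in BASELINE_DISTS:
                mode, val, onset = subj_eff[name]
                base = baselines[name]
                if onset is None:
                    clean[name] = np.full_like(time, base)
                elif mode == "r":
                    clean[name] = base * (1.0 + (val - 1.0) * onset)
                else:
                    clean[name] = base + val * onset

            # systemic noise shared across hemispheres
            sys_noise = {
                name: _ar1(rng, noise.ar1_coeff[name], noise.sd[name], (time.size,))
                for name in SYSTEMIC_CHANNELS
            }
            for hemi in ("left", "right"):
                channels: dict[str, np.ndarray] = {}
                for name in CEREBRAL_CHANNELS:
                    x = clean[name].copy()
                    if lateralized and hemi == "right":
                        x = np.full_like(time, baselines[name])
                    x = x + _ar1(rng, noise.ar1_coeff[name], noise.sd[name], (time.size,))
                    channels[name] = x
                for name in SYSTEMIC_CHANNELS:
                    channels[name] = clean[name] + sys_noise[name]
                channels["SpO2"] = np.clip(channels["SpO2"], 0.0, 100.0)
                channels["StO2"] = np.clip(channels["StO2"], 0.0, 100.0)
                series.append(
                    PhysioSeries(
                        subject_id=subj,
                        mask_type=mask,
                        hemisphere=hemi,
                        time=time.copy(),
                        channels=channels,
                        meta={
                            "bfi_per_cbf": bfi_baseline / baselines["CBF"],
                            "cbf_baseline": baselines["CBF"],
                            "injected": {
                                name: subj_eff[name][1] for name in BASELINE_DISTS
                            },
                        },
                    )
                )
    return series


# ---------------------------------------------------------------------------
# raw-level optical streams


DEFAULT_MUSP = {690.0: 1.1, 785.0: 1.0, 830.0: 0.9}  # 1/mm, typical adult head
DEFAULT_RHO_NIRS = 25.0  # mm
DEFAULT_RHO_DCS = 25.0  # mm
DCS_WAVELENGTH = 785.0


def default_irf(t_bins: np.ndarray, center_ps: float = 500.0, sigma_ps: float = 60.0) -> np.ndarray:
    """A Gaussian instrument response on the given bins (unit area counts)."""
    irf = np.exp(-0.5 * ((t_bins - center_ps) / sigma_ps) ** 2)
    return irf / irf.sum() * 1e6


def _g2_noise_sigma(
    g1: np.ndarray, beta: float, tau: np.ndarray, noise: NoiseSpec
) -> np.ndarray:
    """Lag-dependent Gaussian SD of g2 noise, photon-count parameterized.

    A simplified correlation-noise model: variance shrinks with the number
    of independent correlator samples ``t_avg / T_bin`` and carries a shot
    term from the photons per bin time ``n = count_rate * T_bin``; the
    correlated term scales with the undecayed fraction of g2.
    """
    t_bin = tau[0]
    n_samples = noise.dcs_t_avg / t_bin
    n_photons = noise.dcs_count_rate * t_bin
    var = (1.0 + beta**2 * g1**4 + 2.0 * beta * g1**2 / max(n_photons, 1e-12)) / n_samples
    return np.sqrt(var)


def simulate_raw_optics(
    series: PhysioSeries,
    noise: NoiseSpec | None = None,
    cadence_s: float = 1.0,
    rng: np.random.Generator | None = None,
    table: ExtinctionTable = DEFAULT_EXTINCTION_TABLE,
    beta: float = 0.5,
    noiseless: bool = False,
    tau: np.ndarray | None = None,
    t_bins: np.ndarray | None = None,
) -> tuple[np.ndarray, list[G2Curve], list[dict[float, DTOF]]]:
    """Raw g2 and DTOF streams driven by one physiological series.

    At each acquisition time the underlying BFi is scaled from the CBF
    channel (``meta['bfi_per_cbf']``), and per-wavelength absorption is
    computed from the HbO/HbR implied by the StO2 and tHb channels plus the
    water term. Returns ``(times, g2_curves, dtofs_by_wavelength)``.
    """
    noise = noise or NoiseSpec()
    rng = rng or np.random.default_rng(0)
    for k in ("CBF", "StO2", "tHb"):
        if k not in series.channels:
            raise ValidationError(f"series lacks underlying channel {k}")
    if "bfi_per_cbf" not in series.meta:
        raise ValidationError("series lacks BFi scaling metadata (meta['bfi_per_cbf'])")
    if noise.dtof_total_counts < 1:
        raise ValidationError("DTOF acquisition with zero counts")

    tau = np.logspace(-7, -2, 64) if tau is None else np.asarray(tau, dtype=float)
    t_bins = (np.arange(400) * 10.0 + 5.0) if t_bins is None else np.asarray(t_bins, float)
    irf = default_irf(t_bins)
    bin_width = float(t_bins[1] - t_bins[0])
    k0 = wavenumber_in_medium(DCS_WAVELENGTH)
    geom_dcs = Geometry(rho=DEFAULT_RHO_DCS)
    geom_nirs = Geometry(rho=DEFAULT_RHO_NIRS)

    step = max(1, int(round(cadence_s / series.dt)))
    idx = np.arange(0, series.time.size, step)
    times = series.time[idx]
    g2_curves: list[G2Curve] = []
    dtofs: list[dict[float, DTOF]] = []
    for i in idx:
        cbf = series.channels["CBF"][i]
        sto2 = series.channels["StO2"][i]
        thb = series.channels["tHb"][i]
        bfi = max(series.meta["bfi_per_cbf"] * cbf, 0.0)
        hbo = thb * sto2 / 100.0
        hbr = thb - hbo
        mua = mua_from_concentrations(hbo, hbr, table)

        dtof_set: dict[float, DTOF] = {}
        for wl, mua_wl in mua.items():
            op = OpticalProperties(mua=mua_wl, musp=DEFAULT_MUSP[wl], wavelength=wl)
            refl = td_reflectance(op, geom_nirs, t_bins)
            model = convolve_irf(refl, irf, bin_width)
            lam = model / model.sum() * noise.dtof_total_counts
            counts = lam if noiseless else rng.poisson(lam).astype(float)
            dtof_set[wl] = DTOF(t_bins=t_bins, counts=counts, irf=irf, wavelength=wl)
        dtofs.append(dtof_set)

        op_dcs = OpticalProperties(
            mua=mua[DCS_WAVELENGTH], musp=DEFAULT_MUSP[DCS_WAVELENGTH], wavelength=DCS_WAVELENGTH
        )
        g1 = g1_semiinf(op_dcs, geom_dcs, bfi, k0, tau)
        g2 = g2_from_g1(g1, beta)
        if not noiseless:
            g2 = g2 + rng.normal(0.0, _g2_noise_sigma(g1, beta, tau, noise))
        g2_curves.append(G2Curve(tau=tau, g2=g2, beta=beta, count_rate=noise.dcs_count_rate))
    return times, g2_curves, dtofs
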