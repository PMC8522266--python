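"""The within-subject mask-study analysis pipeline.

Processing chain per subject and mask condition:

1. artifact detection (robust z-score against a rolling median/MAD),
2. exclusion of the mask-placement interval,
3. 30-s centered moving-average smoothing over valid samples,
4. hemisphere averaging (after a paired Wilcoxon check that left and right
   do not differ),
5. baseline normalization (ratio or difference per parameter) and epoch
   means over the analysis window,
6. paired change estimation across subjects with two-sided t-based
   confidence intervals, per mask and between masks.

Derived channels (OEF and relative CMRO2) are computed from the smoothed
StO2, CBF and SpO2 series inside the epoching step, so they inherit the
same artifact handling.

Time convention: seconds, 0 = start of mask placement, negative = pre-mask
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .forward_models import ValidationError
from .hemodynamics import MODE_BY_PARAM, oef as oef_fn

__all__ = [
    "EpochDesign",
    "PhysioSeries",
    "StudyResult",
    "CEREBRAL_CHANNELS",
    "SYSTEMIC_CHANNELS",
    "ANALYSIS_PARAMS",
    "detect_artifacts",
    "smooth",
    "merge_hemispheres",
    "hemisphere_side_test",
    "epoch_changes",
    "paired_estimate",
    "between_mask_estimate",
    "analyze_study",
]

CEREBRAL_CHANNELS = ("CBF", "StO2", "tHb")
SYSTEMIC_CHANNELS = ("MAP", "HR", "RR", "SpO2", "TcCO2", "EtCO2")
#: Parameters reported in the results table (EtCO2 only when enabled).
ANALYSIS_PARAMS = ("CBF", "StO2", "tHb", "OEF", "CMRO2", "MAP", "HR", "RR", "SpO2", "TcCO2")

MASK_TYPES = ("FFP2", "surgical")


@dataclass(frozen=True)
class EpochDesign:
    """Study epoch timing in seconds relative to mask placement.

    Baseline covers the 300 s before mask-on; samples during mask placement
    are excluded; the analysis window starts at the 3-min mark (to let
    physiology stabilize) and runs to the end of the 10-min mask epoch.
    """

    baseline: tuple[float, float] = (-300.0, 0.0)
    exclusion: tuple[float, float] = (0.0, 30.0)
    analysis: tuple[float, float] = (180.0, 600.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("baseline", self.baseline),
            ("exclusion", self.exclusion),
            ("analysis", self.analysis),
        ):
            if hi <= lo:
                raise ValidationError(f"{name} window has non-positive length")
        if not (self.baseline[1] <= self.exclusion[0] <= self.exclusion[1] <= self.analysis[0]):
            raise ValidationError("epoch windows must be ordered baseline < exclusion < analysis")


@dataclass
class PhysioSeries:
    """A timestamped multi-channel physiological series.

    ``channels`` maps channel name to a float array on the shared time base;
    ``valid`` maps channel name to a boolean mask (True = usable sample).
    NaN samples are always treated as invalid.
    """

    subject_id: str
    mask_type: str
    hemisphere: str
    time: np.ndarray
    channels: dict[str, np.ndarray]
    valid: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValidationError(f"time must be strictly increasing (subject {self.subject_id})")
        for name, x in self.channels.items():
            x = np.asarray(x, dtype=float)
            if x.shape != self.time.shape:
                raise ValidationError(f"channel {name} length mismatch")
            self.channels[name] = x
        for name in self.channels:
            v = self.valid.get(name)
            v = np.ones(self.time.shape, bool) if v is None else np.asarray(v, bool)
            self.valid[name] = v & np.isfinite(self.channels[name])

    def copy(self) -> "PhysioSeries":
        return PhysioSeries(
            subject_id=self.subject_id,
            mask_type=self.mask_type,
            hemisphere=self.hemisphere,
            time=self.time.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            valid={k: v.copy() for k, v in self.valid.items()},
            meta=dict(self.meta),
        )

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class StudyResult:
    """A per-parameter paired change estimate with its confidence interval.

    For ratio-mode parameters the estimate and CI are reported as percent
    change, ``(mean ratio - 1) * 100``.
    """

    parameter: str
    mask_type: str  # a mask label or "between-mask"
    mode: str  # "r" or "delta"
    point_estimate: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_subjects: int
    significant: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point_estimate <= self.ci_high):
            raise ValidationError("CI must bracket the point estimate")
        if self.n_subjects < 2:
            raise ValidationError("need >= 2 subjects")


# ---------------------------------------------------------------------------
# per-series operations


def detect_artifacts(
    series: PhysioSeries,
    window_s: float = 15.0,
    threshold: float = 5.0,
    channels: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Flag samples whose robust z-score versus a rolling median exceeds threshold.

    The scale is the rolling median absolute deviation (MAD), scaled by
    1.4826 to be consistent with a Gaussian standard deviation. Returns a
    dict of boolean arrays (True = artifact) and marks the flagged samples
    invalid on the series in place.

    Raises when a channel has no valid samples at all.
    """
    nwin = max(3, int(round(window_s / series.dt)) | 1)  # odd, >= 3
    flags: dict[str, np.ndarray] = {}
    for name in channels or series.channels:
        x = series.channels[name]
        finite = np.isfinite(x)
        if not finite.any():
            raise ValidationError(
                f"channel {name} of subject {series.subject_id} has no valid samples"
            )
        xf = np.where(finite, x, np.nanmedian(x[finite]))
        med = ndimage.median_filter(xf, size=nwin, mode="nearest")
        dev = np.abs(xf - med)
        mad = ndimage.median_filter(dev, size=nwin, mode="nearest")
        scale = 1.4826 * mad
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(scale > 0, dev / scale, np.where(dev > 0, np.inf, 0.0))
        flag = (z > threshold) & finite
        flags[name] = flag
        series.valid[name] &= ~flag
    return flags


def exclude_interval(series: PhysioSeries, lo: float, hi: float) -> None:
    """Mark all samples with lo <= t < hi invalid on every channel (in place)."""
    inside = (series.time >= lo) & (series.time < hi)
    for name in series.valid:
        series.valid[name] &= ~inside


def _moving_average(x: np.ndarray, valid: np.ndarray, nwin: int) -> np.ndarray:
    kernel = np.ones(nwin)
    xv = np.where(valid, x, 0.0)
    sums = np.convolve(xv, kernel, mode="same")
    counts = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def smooth(series: PhysioSeries, window_s: float = 30.0) -> PhysioSeries:
    """Centered moving average over valid samples within +/- window_s/2.

    Returns a new series; samples with no valid neighbour in the window
    become NaN (and invalid). Invalid samples that gain a smoothed value
    stay invalid.
    """
    if window_s <= 0:
        raise ValidationError("smoothing window must be positive")
    nwin = max(1, int(round(window_s / series.dt)) | 1)
    out = series.copy()
    for name, x in series.channels.items():
        sm = _moving_average(x, series.valid[name], nwin)
        out.channels[name] = sm
        out.valid[name] = series.valid[name] & np.isfinite(sm)
    return out


# ---------------------------------------------------------------------------
# hemisphere handling


def _pairwise_merge(left: PhysioSeries, right: PhysioSeries) -> PhysioSeries:
    if left.time.shape != right.time.shape or not np.allclose(left.time, right.time):
        raise ValidationError(
            f"mismatched time bases for subject {left.subject_id} hemispheres"
        )
    merged = left.copy()
    merged.hemisphere = "merged"
    for name in left.channels:
        lx, rx = left.channels[name], right.channels[name]
        lv, rv = left.valid[name], right.valid[name]
        both = lv & rv
        out = np.full_like(lx, np.nan)
        out[both] = 0.5 * (lx[both] + rx[both])
        only_l = lv & ~rv
        only_r = rv & ~lv
        out[only_l] = lx[only_l]
        out[only_r] = rx[only_r]
        merged.channels[name] = out
        merged.valid[name] = lv | rv
    return merged


def hemisphere_side_test(
    lefts: list[PhysioSeries],
    rights: list[PhysioSeries],
    design: EpochDesign,
    channels: tuple[str, ...] = CEREBRAL_CHANNELS,
) -> dict[str, float]:
    """Paired Wilcoxon signed-rank of left-vs-right epoch-mean changes.

    Pairs are subjects; the tested quantity is the baseline-normalized
    analysis-window mean per cerebral channel. All-zero differences (the
    degenerate tie case) are reported as P = 1 by convention.
    """
    pvals: dict[str, float] = {}
    for name in channels:
        diffs = []
        for l, r in zip(lefts, rights):
            cl = _single_channel_change(l, name, design)
            cr = _single_channel_change(r, name, design)
            diffs.append(cl - cr)
        d = np.asarray(diffs, dtype=float)
        if np.allclose(d, 0.0):
            pvals[name] = 1.0
        else:
            pvals[name] = float(stats.wilcoxon(d).pvalue)
    return pvals


def merge_hemispheres(
    left: PhysioSeries | list[PhysioSeries],
    right: PhysioSeries | list[PhysioSeries],
    design: EpochDesign | None = None,
    alpha: float = 0.05,
) -> tuple[list[PhysioSeries], dict[str, float]]:
    """Average left and right hemispheres after a side-difference check.

    Accepts single series or matched lists (one entry per subject). The
    Wilcoxon side test requires a design; when omitted, only the merge is
    performed (P-values reported as NaN). Merging proceeds even when the
    side test is significant, but a warning is raised.
    """
    lefts = [left] if isinstance(left, PhysioSeries) else list(left)
    rights = [right] if isinstance(right, PhysioSeries) else list(right)
    if len(lefts) != len(rights):
        raise ValidationError("left and right lists must be matched per subject")
    for l, r in zip(lefts, rights):
        if l.subject_id != r.subject_id:
            raise ValidationError("hemisphere pairs must share subject ids")
    if design is not None and len(lefts) >= 2:
        pvals = hemisphere_side_test(lefts, rights, design)
        for name, p in pvals.items():
            if p < alpha:
                warnings.warn(
                    f"hemispheres differ for channel {name} (Wilcoxon P={p:.3g}); "
                    "merging anyway",
                    stacklevel=2,
                )
    else:
        pvals = {name: float("nan") for name in CEREBRAL_CHANNELS}
    merged = [_pairwise_merge(l, r) for l, r in zip(lefts, rights)]
    return merged, pvals


# ---------------------------------------------------------------------------
# epoching and normalization


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (time >= lo) & (time < hi)


def _single_channel_change(
    series: PhysioSeries, name: str, design: EpochDesign
) -> float:
    """Baseline-normalized analysis-window mean for one raw channel."""
    mode = MODE_BY_PARAM.get(name, "delta")
    x = series.channels[name]
    v = series.valid[name]
    bmask = _window_mask(series.time, design.baseline) & v
    amask = _window_mask(series.time, design.analysis) & v
    if not bmask.any():
        raise ValidationError(f"subject {series.subject_id}: empty baseline window for {name}")
    if not amask.any():
        raise ValidationError(f"subject {series.subject_id}: empty analysis window for {name}")
    b = x[bmask].mean()
    a = x[amask].mean()
    return a / b if mode == "r" else a - b


def epoch_changes(
    series: PhysioSeries,
    design: EpochDesign,
    gamma: float = 0.75,
    normalized_series: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Per-subject change values for every analysis parameter.

    Raw channels are normalized per their declared mode (ratio for CBF,
    difference for the rest) and averaged over the analysis window. The
    derived channels are computed from the smoothed series:

    * OEF(t) from StO2(t) and SpO2(t) with the venous fraction ``gamma``;
      reported as a difference in percentage points.
    * CMRO2 via the Fick principle,
      ``rCMRO2(t) = rCBF(t) * OEF(t)/OEF_0 * SaO2(t)/SaO2_0``; reported as
      a ratio.

    EtCO2 is computed like any difference channel but is tagged
    excluded-by-default downstream (the in-mask probe reads trapped air).

    When ``normalized_series`` is a dict it is filled with the normalized
    full-length series (for population time-course output).
    """
    time, v = series.time, series.valid
    bmask_t = _window_mask(time, design.baseline)
    amask_t = _window_mask(time, design.analysis)

    def win_mean(x: np.ndarray, valid: np.ndarray, wmask: np.ndarray, label: str) -> float:
        m = wmask & valid & np.isfinite(x)
        if not m.any():
            raise ValidationError(
                f"subject {series.subject_id}: empty {label} window"
            )
        return float(x[m].mean())

    changes: dict[str, float] = {}
    norm: dict[str, np.ndarray] = {}

    for name in CEREBRAL_CHANNELS + SYSTEMIC_CHANNELS:
        if name not in series.channels:
            continue
        x = series.channels[name]
        mode = MODE_BY_PARAM[name]
        b = win_mean(x, v[name], bmask_t, "baseline")
        xa = x / b if mode == "r" else x - b
        norm[name] = np.where(v[name], xa, np.nan)
        changes[name] = win_mean(xa, v[name], amask_t, "analysis")

    # derived channels from smoothed StO2 / SpO2 / CBF
    if all(k in series.channels for k in ("StO2", "SpO2", "CBF")):
        sto2, spo2, cbf = (series.channels[k] for k in ("StO2", "SpO2", "CBF"))
        dv = v["StO2"] & v["SpO2"] & v["CBF"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oef_t = oef_fn(np.where(dv, sto2, np.nan), np.where(dv, np.clip(spo2, 1e-6, 100.0), 100.0), gamma)
        sto2_0 = win_mean(sto2, v["StO2"], bmask_t, "baseline")
        spo2_0 = win_mean(spo2, v["SpO2"], bmask_t, "baseline")
        cbf_0 = win_mean(cbf, v["CBF"], bmask_t, "baseline")
        oef_0 = float(oef_fn(sto2_0, spo2_0, gamma))
        if oef_0 <= 0:
            raise ValidationError(f"subject {series.subject_id}: zero baseline OEF")
        # OEF reported in percentage points
        d_oef = (oef_t - oef_0) * 100.0
        norm["OEF"] = np.where(dv, d_oef, np.nan)
        changes["OEF"] = win_mean(d_oef, dv, amask_t, "analysis")
        rcbf_t = cbf / cbf_0
        rcmro2_t = rcbf_t * (oef_t / oef_0) * (spo2 / spo2_0)
        norm["CMRO2"] = np.where(dv, rcmro2_t, np.nan)
        changes["CMRO2"] = win_mean(rcmro2_t, dv, amask_t, "analysis")

    if normalized_series is not None:
        normalized_series.update(norm)
    return changes


# ---------------------------------------------------------------------------
# population statistics


def _t_interval(values: np.ndarray, ci_level: float) -> tuple[float, float, float]:
    n = values.size
    m = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        return m, m, m
    half = stats.t.ppf(0.5 + ci_level / 2.0, n - 1) * sd / np.sqrt(n)
    return m, m - half, m + half


def _wilcoxon_interval(values: np.ndarray, ci_level: float) -> tuple[float, float, float]:
    """Hodges-Lehmann estimate with a Walsh-average quantile interval."""
    n = values.size
    walsh = [(values[i] + values[j]) / 2.0 for i in range(n) for j in range(i, n)]
    walsh = np.sort(np.asarray(walsh))
    m = float(np.median(walsh))
    alpha = 1.0 - ci_level
    lo = float(np.quantile(walsh, alpha / 2.0))
    hi = float(np.quantile(walsh, 1.0 - alpha / 2.0))
    return m, min(lo, m), max(hi, m)


def paired_estimate(
    changes: np.ndarray | list[float],
    null_value: float,
    parameter: str = "",
    mask_type: str = "",
    mode: str = "delta",
    ci_level: float = 0.95,
    method: str = "t",
) -> StudyResult:
    """Mean change across subjects with a two-sided t-based confidence interval.

    ``null_value`` is 0 for difference-mode and 1 for ratio-mode parameters;
    significance means the CI excludes it. Ratio-mode results are reported
    as percent change, ``(mean - 1) * 100``, with the CI transformed the
    same way. ``method='wilcoxon'`` switches to a Hodges-Lehmann estimate
    with a signed-rank-style interval.
    """
    values = np.asarray(changes, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValidationError("paired estimate needs >= 2 finite values")
    est = _t_interval if method == "t" else _wilcoxon_interval
    m, lo, hi = est(values, ci_level)
    significant = not (lo <= null_value <= hi)
    if lo == hi == null_value:
        significant = False
    if mode == "r":
        m, lo, hi = (m - 1.0) * 100.0, (lo - 1.0) * 100.0, (hi - 1.0) * 100.0
    return StudyResult(
        parameter=parameter,
        mask_type=mask_type,
        mode=mode,
        point_estimate=m,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        n_subjects=int(values.size),
        significant=bool(significant),
    )


def between_mask_estimate(
    changes_a: dict[str, float],
    changes_b: dict[str, float],
    parameter: str = "",
    mode: str = "delta",
    ci_level: float = 0.95,
    method: str = "t",
) -> StudyResult:
    """Paired per-subject difference between mask types with a t-based CI.

    ``changes_a``/``changes_b`` map subject id to the per-subject change
    value under each mask; subjects must match. Ratio-mode changes are
    differenced on the percent-change scale.
    """
    if set(changes_a) != set(changes_b):
        missing = set(changes_a) ^ set(changes_b)
        raise ValidationError(f"unpaired subjects between masks: {sorted(missing)}")
    subjects = sorted(changes_a)
    a = np.asarray([changes_a[s] for s in subjects], dtype=float)
    b = np.asarray([changes_b[s] for s in subjects], dtype=float)
    if mode == "r":
        a = (a - 1.0) * 100.0
        b = (b - 1.0) * 100.0
    diffs = a - b
    result = paired_estimate(
        diffs,
        null_value=0.0,
        parameter=parameter,
        mask_type="between-mask",
        mode="delta",
        ci_level=ci_level,
        method=method,
    )
    return replace(result, mode=mode)


# ---------------------------------------------------------------------------
# the full study


def analyze_study(
    series_list: list[PhysioSeries],
    design: EpochDesign | None = None,
    *,
    smoothing_window_s: float = 30.0,
    artifact_threshold: float = 5.0,
    artifact_window_s: float = 15.0,
    ci_level: float = 0.95,
    gamma: float = 0.75,
    include_etco2: bool = False,
    method: str = "t",
    compute_timecourses: bool = True,
    log: list[str] | None = None,
) -> tuple[list[StudyResult], dict]:
    """Run the full pipeline on a set of per-subject hemisphere series.

    Input series are raw (unsmoothed) per subject/mask/hemisphere. Returns
    the per-mask and between-mask :class:`StudyResult` rows and a summary
    dict with per-subject changes, hemisphere-test P-values and (optionally)
    population-mean normalized time courses.
    """
    design = design or EpochDesign()
    log = log if log is not None else []

    by_key: dict[tuple[str, str], dict[str, PhysioSeries]] = {}
    for s in series_list:
        by_key.setdefault((s.subject_id, s.mask_type), {})[s.hemisphere] = s
    mask_types = sorted({k[1] for k in by_key}, key=str)

    changes: dict[str, dict[str, dict[str, float]]] = {m: {} for m in mask_types}
    side_pvals: dict[str, dict[str, float]] = {}
    timecourses: dict[str, dict[str, np.ndarray]] = {}

    for mask in mask_types:
        subjects = sorted(s for (s, m) in by_key if m == mask)
        lefts, rights = [], []
        for subj in subjects:
            hemis = by_key[(subj, mask)]
            processed = {}
            for hemi, raw in hemis.items():
                s = raw.copy()
                flags = detect_artifacts(
                    s, window_s=artifact_window_s, threshold=artifact_threshold
                )
                nflag = int(sum(f.sum() for f in flags.values()))
                if nflag:
                    log.append(
                        f"artifact: subject={subj} mask={mask} hemi={hemi} samples={nflag}"
                    )
                exclude_interval(s, *design.exclusion)
                processed[hemi] = smooth(s, smoothing_window_s)
            if {"left", "right"} <= set(processed):
                lefts.append(processed["left"])
                rights.append(processed["right"])
            elif "merged" in processed:
                lefts.append(processed["merged"])
                rights.append(processed["merged"])
            else:
                only = next(iter(processed.values()))
                lefts.append(only)
                rights.append(only)
        merged, pvals = merge_hemispheres(lefts, rights, design)
        side_pvals[mask] = pvals
        log.append(
            "hemisphere Wilcoxon P: "
            + ", ".join(f"{k}={v:.3g}" for k, v in pvals.items())
            + f" (mask={mask})"
        )

        tc_accum: dict[str, list[np.ndarray]] = {}
        for s in merged:
            norm: dict[str, np.ndarray] = {}
            ch = epoch_changes(s, design, gamma=gamma, normalized_series=norm)
            changes[mask][s.subject_id] = ch
            if compute_timecourses:
                for name, arr in norm.items():
                    tc_accum.setdefault(name, []).append(arr)
        if compute_timecourses and merged:
            with warnings.catch_warnings():
                # all-NaN columns (e.g. the excluded placement interval) are fine
                warnings.simplefilter("ignore", category=RuntimeWarning)
                timecourses[mask] = {
                    "time": merged[0].time,
                    **{
                        name: np.nanmean(np.vstack(arrs), axis=0)
                        for name, arrs in tc_accum.items()
                    },
                }

    params = list(ANALYSIS_PARAMS) + (["EtCO2"] if include_etco2 else [])
    log.append(
        "EtCO2 included by config"
        if include_etco2
        else "EtCO2 excluded by default (in-mask probe artifact)"
    )
    results: list[StudyResult] = []
    for mask in mask_types:
        for param in params:
            vals = {
                subj: ch[param]
                for subj, ch in changes[mask].items()
                if param in ch and np.isfinite(ch[param])
            }
            if len(vals) < 2:
                log.append(f"skipped: {param} mask={mask} (<2 subjects)")
                continue
            mode = MODE_BY_PARAM[param]
            results.append(
                paired_estimate(
                    list(vals.values()),
                    null_value=1.0 if mode == "r" else 0.0,
                    parameter=param,
                    mask_type=mask,
                    mode=mode,
                    ci_level=ci_level,
                    method=method,
                )
            )
    if len(mask_types) == 2:
        ma, mb = mask_types
        # report FFP2 - surgical when both present, regardless of sort order
        if "FFP2" in mask_types and "surgical" in mask_types:
            ma, mb = "FFP2", "surgical"
        for param in params:
            a = {s: ch[param] for s, ch in changes[ma].items() if param in ch}
            b = {s: ch[param] for s, ch in changes[mb].items() if param in ch}
            common = set(a) & set(b)
            if len(common) < 2:
                continue
            results.append(
                between_mask_estimate(
                    {s: a[s] for s in common},
                    {s: b[s] for s in common},
                    parameter=param,
                    mode=MODE_BY_PARAM[param],
                    ci_level=ci_level,
                    method=method,
                )
            )

    summary = {
        "changes": changes,
        "side_pvals": side_pvals,
        "timecourses": timecourses,
        "log": log,
    }
    return results, summary
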