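"""Readers, writers and study configuration.

Physiological series travel as UTF-8 TSV files with ``#``-prefixed metadata
header lines (subject, mask, hemisphere, units), a header row
(``time_s`` + channel columns) and NaN for missing samples. The reader also
accepts comma-delimited files and a column-mapping so externally named
deposits can be ingested.

The study configuration (epoch timing, normalization modes, fit and
statistics settings) round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forward_models import ValidationError
from .hemodynamics import MODE_BY_PARAM
from .pipeline import (
    CEREBRAL_CHANNELS,
    SYSTEMIC_CHANNELS,
    EpochDesign,
    PhysioSeries,
    StudyResult,
    analyze_study,
)

__all__ = [
    "StudyConfig",
    "read_physio_tsv",
    "write_physio_tsv",
    "results_to_frame",
    "write_results_tsv",
    "write_timecourses_tsv",
    "run_pipeline",
]

KNOWN_CHANNELS = set(CEREBRAL_CHANNELS) | set(SYSTEMIC_CHANNELS)


@dataclass
class StudyConfig:
    """Everything the pipeline needs besides the data files."""

    subjects: list[str] = field(default_factory=list)
    mask_types: list[str] = field(default_factory=lambda: ["FFP2", "surgical"])
    hemispheres: list[str] = field(default_factory=lambda: ["left", "right"])
    baseline: tuple[float, float] = (-300.0, 0.0)
    exclusion: tuple[float, float] = (0.0, 30.0)
    analysis: tuple[float, float] = (180.0, 600.0)
    modes: dict = field(default_factory=lambda: dict(MODE_BY_PARAM))
    smoothing_window_s: float = 30.0
    artifact_threshold: float = 5.0
    artifact_window_s: float = 15.0
    ci_level: float = 0.95
    gamma: float = 0.75
    include_etco2: bool = False
    method: str = "t"  # "t" or "wilcoxon"
    resample_hz: float = 1.0
    delimiter: str = "\t"
    column_map: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.design  # validates window ordering

    @property
    def design(self) -> EpochDesign:
        return EpochDesign(
            baseline=tuple(self.baseline),
            exclusion=tuple(self.exclusion),
            analysis=tuple(self.analysis),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["baseline"] = list(self.baseline)
        d["exclusion"] = list(self.exclusion)
        d["analysis"] = list(self.analysis)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def write_physio_tsv(series: PhysioSeries, path: str | Path) -> None:
    """Write a series as TSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    names = list(series.channels)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject: {series.subject_id}\n")
        fh.write(f"# mask_type: {series.mask_type}\n")
        fh.write(f"# hemisphere: {series.hemisphere}\n")
        fh.write("# time: s relative to mask placement (0 = mask-on)\n")
        fh.write("time_s\t" + "\t".join(names) + "\n")
        cols = [series.time] + [
            np.where(series.valid[n], series.channels[n], np.nan) for n in names
        ]
        for row in zip(*cols):
            fh.write("\t".join(f"{v:.6g}" if np.isfinite(v) else "nan" for v in row) + "\n")


def read_physio_tsv(
    path: str | Path,
    delimiter: str = "\t",
    column_map: dict[str, str] | None = None,
) -> PhysioSeries:
    """Read a physiological series TSV written by :func:`write_physio_tsv`.

    ``column_map`` renames external column headers to the package's channel
    names (e.g. ``{"rCBF": "CBF"}``) before validation. Unknown channels
    raise a warning but are kept; non-monotone time raises with the
    offending line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep=delimiter, comment="#", na_values=["nan", "NaN", "NA"])
    if column_map:
        df = df.rename(columns=column_map)
    if "time_s" not in df.columns:
        raise ValidationError(f"{path}: missing 'time_s' column")
    time = df["time_s"].to_numpy(float)
    bad = np.nonzero(np.diff(time) <= 0)[0]
    if bad.size:
        # +2 for header row and 1-based numbering, + metadata lines
        lineno = int(bad[0]) + 2 + header_lines + 1
        raise ValidationError(f"{path}: non-monotone time at line {lineno}")
    channels = {}
    for col in df.columns:
        if col == "time_s":
            continue
        if col not in KNOWN_CHANNELS:
            warnings.warn(f"{path.name}: unknown channel {col!r}", stacklevel=2)
        channels[col] = df[col].to_numpy(float)
    return PhysioSeries(
        subject_id=meta.get("subject", path.stem),
        mask_type=meta.get("mask_type", "unknown"),
        hemisphere=meta.get("hemisphere", "merged"),
        time=time,
        channels=channels,
        meta=meta,
    )


def resample_series(series: PhysioSeries, fs_hz: float) -> PhysioSeries:
    """Linearly interpolate all channels onto a common uniform grid."""
    t0, t1 = series.time[0], series.time[-1]
    dt = 1.0 / fs_hz
    grid = np.arange(np.ceil(t0 / dt) * dt, t1 + 1e-9, dt)
    channels = {}
    for name, x in series.channels.items():
        good = series.valid[name]
        if good.sum() >= 2:
            channels[name] = np.interp(grid, series.time[good], x[good])
        else:
            channels[name] = np.full(grid.shape, np.nan)
    return PhysioSeries(
        subject_id=series.subject_id,
        mask_type=series.mask_type,
        hemisphere=series.hemisphere,
        time=grid,
        channels=channels,
        meta=dict(series.meta),
    )


def results_to_frame(results: list[StudyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "mask_type": r.mask_type,
                "mode": r.mode,
                "estimate": r.point_estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "ci_level": r.ci_level,
                "n_subjects": r.n_subjects,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def write_results_tsv(results: list[StudyResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_timecourses_tsv(timecourses: dict, path: str | Path) -> None:
    """Population-mean normalized time courses, one column per (parameter, mask)."""
    frames = []
    for mask, tc in timecourses.items():
        df = pd.DataFrame({"time_s": tc["time"]})
        for name, arr in tc.items():
            if name == "time":
                continue
            df[f"{name}_{mask}"] = arr
        frames.append(df.set_index("time_s"))
    out = pd.concat(frames, axis=1).reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    config: StudyConfig,
    data_dir: str | Path,
    out_dir: str | Path | None = None,
) -> tuple[list[StudyResult], dict]:
    """Read all configured subject files, analyze, and write results.

    Expects one TSV per subject/mask/hemisphere named
    ``{subject}_{mask}_{hemisphere}.tsv``. Missing files raise an error
    listing every absent path. Outputs (when ``out_dir`` given):
    ``results.tsv``, ``timecourses.tsv`` and ``pipeline.log`` (one line per
    exclusion/processing decision).
    """
    data_dir = Path(data_dir)
    if not config.subjects:
        found = sorted(data_dir.glob("*.tsv"))
        subjects = sorted({p.stem.split("_")[0] for p in found})
    else:
        subjects = list(config.subjects)
    paths = [
        data_dir / f"{s}_{m}_{h}.tsv"
        for s in subjects
        for m in config.mask_types
        for h in config.hemispheres
    ]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise ValidationError("missing data files: " + ", ".join(missing))

    log: list[str] = [f"subjects: {', '.join(subjects)}"]
    series = []
    for p in paths:
        s = read_physio_tsv(p, delimiter=config.delimiter, column_map=config.column_map)
        s = resample_series(s, config.resample_hz)
        series.append(s)
        log.append(f"read: {p.name} ({s.time.size} samples after resampling)")

    results, summary = analyze_study(
        series,
        design=config.design,
        smoothing_window_s=config.smoothing_window_s,
        artifact_threshold=config.artifact_threshold,
        artifact_window_s=config.artifact_window_s,
        ci_level=config.ci_level,
        gamma=config.gamma,
        include_etco2=config.include_etco2,
        method=config.method,
        log=log,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results_tsv(results, out_dir / "results.tsv")
        if summary["timecourses"]:
            write_timecourses_tsv(summary["timecourses"], out_dir / "timecourses.tsv")
        (out_dir / "pipeline.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return results, summary
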