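"""Batch analysis pipeline and CSV reporting.

`analyze_image` chains load -> (transpose) -> crop -> bilateral smooth ->
full-ROI transient analysis -> per-slice analysis -> alternans/DI, and
packs the results into pandas tables matching the tool's CSV exports:
a full-cell table (one row per transient), a per-slice table (same
columns plus slice position), an alternans table (per-pair global and
local ratios), and a run log sufficient to reproduce the run.

All times are in ms, amplitudes are dimensionless dF/F0, upstroke
velocities are intensity units per ms. The schema is versioned through a
comment line at the top of every CSV.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .alternans import AlternansReport, alternans_report
from .errors import BatchError, CalscanError, InsufficientDataError, ParameterError
from .io import LineScanImage, Roi, crop, load_image
from .preprocess import SmoothingParams, bilateral_smooth, slice_roi, um_to_pixels
from .transients import PeakParams, TransientRecord, analyze_region, region_trace

__all__ = [
    "AnalysisConfig",
    "ResultTables",
    "analyze_image",
    "analyze_batch",
    "write_tables",
    "write_summary",
]

_SCHEMA = 1


@dataclass(frozen=True)
class AnalysisConfig:
    """Every knob of one analysis run; round-trips through a flat key=value file."""

    kernel_size: int = 0
    sigma: float = 0.0
    slice_width: int | None = None
    slice_width_um: float | None = None
    drop_partial: bool = False
    peaks_dist: int = 70
    threshold_k: float = 0.0
    ms_per_line: float = 4.3
    um_per_pixel: float = 1.0
    roi: tuple[int, int, int, int] | None = None  # pixel_start, pixel_end, line_start, line_end
    transpose: bool = False
    channel_policy: str | int = "mean"
    magnitude: str = "amplitude"
    di_pooled: bool = False
    smooth_before_crop: bool = False

    def __post_init__(self) -> None:
        if self.slice_width is not None and self.slice_width < 1:
            raise ParameterError("slice_width must be >= 1")
        if self.slice_width_um is not None and not self.slice_width_um > 0:
            raise ParameterError("slice_width_um must be > 0")
        if self.peaks_dist < 1:
            raise ParameterError("peaks_dist must be >= 1")
        if not self.ms_per_line > 0:
            raise ParameterError("ms_per_line must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["roi"] is not None:
            d["roi"] = list(d["roi"])
        return d

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(self.to_dict().items()):
                fh.write(f"{key} = {json.dumps(value)}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "AnalysisConfig":
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                kwargs[key.strip()] = json.loads(raw.strip())
        if kwargs.get("roi") is not None:
            kwargs["roi"] = tuple(kwargs["roi"])
        return cls(**kwargs)


@dataclass
class ResultTables:
    """All tables produced for one image."""

    image: str
    full_cell: pd.DataFrame
    slices: pd.DataFrame
    alternans: pd.DataFrame
    report: AlternansReport | None
    run_log: dict
    summary: dict


_TRANSIENT_COLUMNS = {
    "peak_line": lambda r: r.peak_index,
    "peak_time_ms": None,  # filled with times
    "peak_value": lambda r: r.peak_value,
    "baseline_value": lambda r: r.baseline_value,
    "rel_amplitude": lambda r: r.relative_amplitude,
    "time_to_peak_ms": lambda r: r.time_to_peak_ms,
    "time_to_half_ms": lambda r: r.time_to_half_ms,
    "tau_ms": lambda r: r.tau_ms,
    "tau_flagged": lambda r: r.tau_flagged,
    "max_upstroke_per_ms": lambda r: r.max_upstroke,
}


def _records_frame(records: list[TransientRecord], times_ms: np.ndarray) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        row: dict = {"transient": i}
        for col, getter in _TRANSIENT_COLUMNS.items():
            row[col] = float(times_ms[r.peak_index]) if getter is None else getter(r)
        rows.append(row)
    columns = ["transient", *_TRANSIENT_COLUMNS]
    return pd.DataFrame(rows, columns=columns)


def _resolve_slice_width(config: AnalysisConfig, img: LineScanImage) -> int | None:
    if config.slice_width is not None:
        return config.slice_width
    if config.slice_width_um is not None:
        return um_to_pixels(config.slice_width_um, img)
    return None


def analyze_image(
    source: str | os.PathLike | LineScanImage, config: AnalysisConfig
) -> ResultTables:
    """Run the full analysis on one image (path or in-memory raster)."""
    warnings: list[str] = []
    if isinstance(source, LineScanImage):
        img = source
        name = img.source_name or "in-memory"
    else:
        img = load_image(
            source,
            ms_per_line=config.ms_per_line,
            um_per_pixel=config.um_per_pixel,
            channel_policy=config.channel_policy,
            transpose=config.transpose,
        )
        name = img.source_name

    smoothing = SmoothingParams(kernel_size=config.kernel_size, sigma=config.sigma)
    if config.smooth_before_crop and not smoothing.is_noop:
        img = bilateral_smooth(img, smoothing)
    if config.roi is not None:
        ps, pe, ls, le = config.roi
        img = crop(img, Roi(ps, pe, ls, le))
    if not config.smooth_before_crop and not smoothing.is_noop:
        img = bilateral_smooth(img, smoothing)

    params = PeakParams(min_distance=config.peaks_dist, threshold_k=config.threshold_k)
    full = region_trace(img, label="full")
    records = analyze_region(full, params)
    full_table = _records_frame(records, full.times_ms)

    slice_rows = []
    slice_traces = []
    report: AlternansReport | None = None
    width = _resolve_slice_width(config, img)
    if width is not None:
        sliceset = slice_roi(img.full_roi(), width, drop_partial=config.drop_partial)
        for s, roi in enumerate(sliceset.slices):
            trace = region_trace(img, roi, label=str(s))
            slice_traces.append(trace)
            try:
                slice_records = analyze_region(trace, params)
            except CalscanError as exc:
                warnings.append(f"slice {s}: {exc}")
                continue
            frame = _records_frame(slice_records, trace.times_ms)
            frame.insert(1, "slice", s)
            frame.insert(2, "pixel_start", roi.pixel_start)
            frame.insert(3, "pixel_end", roi.pixel_end)
            frame.insert(4, "partial", roi.width < width)
            slice_rows.append(frame)
    try:
        report = alternans_report(full, slice_traces, params, config.magnitude)
        for s, reason in report.excluded_slices:
            warnings.append(f"slice {s} excluded from DI: {reason}")
    except InsufficientDataError as exc:
        warnings.append(f"alternans analysis skipped: {exc}")

    slices_table = (
        pd.concat(slice_rows, ignore_index=True)
        if slice_rows
        else pd.DataFrame(
            columns=["transient", "slice", "pixel_start", "pixel_end", "partial",
                     *_TRANSIENT_COLUMNS]
        )
    )

    alt_rows = []
    if report is not None:
        for p in report.global_pairs:
            alt_rows.append(
                {"scope": "global", "slice": np.nan, "pair": p.pair_index,
                 "first_value": p.first_value, "second_value": p.second_value,
                 "ratio": p.ratio}
            )
        n_slices, n_pairs = report.local_ratios.shape
        for s in range(n_slices):
            for i in range(n_pairs):
                alt_rows.append(
                    {"scope": "local", "slice": s, "pair": i,
                     "first_value": np.nan, "second_value": np.nan,
                     "ratio": report.local_ratios[s, i]}
                )
    alternans_table = pd.DataFrame(
        alt_rows, columns=["scope", "slice", "pair", "first_value", "second_value", "ratio"]
    )

    di = float("nan")
    if report is not None:
        di = report.discordance_index_pooled if config.di_pooled else report.discordance_index
    summary = {
        "image": name,
        "n_peaks": len(records),
        "mean_rel_amplitude": (
            float(np.mean([r.relative_amplitude for r in records])) if records else float("nan")
        ),
        "mean_tau_ms": (
            float(np.nanmean([r.tau_ms for r in records])) if records else float("nan")
        ),
        "global_ar": report.global_ar if report is not None else float("nan"),
        "local_ar": report.local_ar_summary if report is not None else float("nan"),
        "discordance_index": di,
        "n_slices": report.n_slices if report is not None else 0,
        "n_pairs": report.n_pairs if report is not None else 0,
    }
    run_log = {
        "calscan_version": __version__,
        "schema": _SCHEMA,
        "image": name,
        "config": config.to_dict(),
        "warnings": warnings,
    }
    return ResultTables(
        image=name,
        full_cell=full_table,
        slices=slices_table,
        alternans=alternans_table,
        report=report,
        run_log=run_log,
        summary=summary,
    )


def analyze_batch(
    sources: list,
    config: AnalysisConfig,
    roi_overrides: dict[str, tuple[int, int, int, int]] | None = None,
) -> tuple[list[ResultTables], pd.DataFrame, dict[str, str]]:
    """Analyze several images; failures are isolated per image.

    ``roi_overrides`` maps image basenames to per-image ROIs (the batch
    replacement for the interactive cropper). Returns the per-image
    tables, a one-row-per-image summary frame, and the failure map.
    Raises :class:`BatchError` only when every image fails.
    """
    if not sources:
        raise ParameterError("analyze_batch needs at least one image")
    results: list[ResultTables] = []
    failures: dict[str, str] = {}
    for src in sources:
        name = (
            src.source_name if isinstance(src, LineScanImage) else os.path.basename(os.fspath(src))
        )
        cfg = config
        if roi_overrides and name in roi_overrides:
            cfg = dataclasses.replace(config, roi=tuple(roi_overrides[name]))
        try:
            results.append(analyze_image(src, cfg))
        except CalscanError as exc:
            failures[name] = str(exc)
    if not results:
        raise BatchError(failures)
    summary = pd.DataFrame([r.summary for r in results])
    return results, summary, failures


def _write_csv(frame: pd.DataFrame, path: str, header_note: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# calscan v{__version__} schema={_SCHEMA}; {header_note}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def write_tables(result: ResultTables, outdir: str | os.PathLike) -> dict[str, str]:
    """Write one image's tables as CSV plus a JSON run log; returns paths."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    stem = os.path.splitext(result.image)[0] or "image"
    note = "times in ms; amplitudes dimensionless dF/F0; upstroke in intensity/ms"
    paths = {
        "full_cell": os.path.join(outdir, f"{stem}_fullcell.csv"),
        "slices": os.path.join(outdir, f"{stem}_slices.csv"),
        "alternans": os.path.join(outdir, f"{stem}_alternans.csv"),
        "run_log": os.path.join(outdir, f"{stem}_runlog.json"),
    }
    _write_csv(result.full_cell, paths["full_cell"], note)
    _write_csv(result.slices, paths["slices"], note)
    _write_csv(result.alternans, paths["alternans"], "ratios dimensionless in [0, 1]")
    with open(paths["run_log"], "w") as fh:
        json.dump(result.run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def write_summary(summary: pd.DataFrame, outdir: str | os.PathLike) -> str:
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    path = os.path.join(outdir, "summary.csv")
    _write_csv(summary, path, "one row per image")
    return path
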