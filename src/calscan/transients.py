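"""Fluorescence-vs-time traces, peak detection and per-transient kinetics.

A region (the full ROI or one spatial slice) is reduced to a 1-D trace by
averaging intensity over its pixels at each scan line. Calcium transients
are located on that trace as local maxima of the first-order difference
sequence (a + to non-positive sign change), filtered by an intensity
threshold derived from the trace average and thinned so no two accepted
peaks are closer than a minimum distance. Each transient is then
characterised by:

* relative amplitude dF/F0 = (peak - baseline) / baseline, with the
  baseline F0 taken at the local minimum preceding the peak;
* time to peak and time to half amplitude on the upstroke (linear
  interpolation between bracketing samples);
* maximal upstroke velocity +dF/dt;
* the decay constant tau of a mono-exponential fit to the segment from
  the peak to the next minimum, by least squares on the linearized
  (log-transformed, floor-subtracted) decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import (
    AmplitudeUndefinedError,
    BoundsError,
    InsufficientDataError,
    ParameterError,
    TauUndefinedError,
)
from .io import LineScanImage, Roi

__all__ = [
    "RegionTrace",
    "PeakParams",
    "TransientRecord",
    "Kinetics",
    "TauFit",
    "PEAKS_DIST_BY_HZ",
    "region_trace",
    "detect_peaks",
    "transient_bounds",
    "relative_amplitude",
    "kinetics",
    "decay_tau",
    "analyze_region",
]

#: Suggested minimum peak distance (in lines) per pacing frequency, for
#: acquisitions at ~4.3 ms/line. Convenience presets, not enforced.
PEAKS_DIST_BY_HZ = {1: 200, 3: 70, 4: 50, 5: 40}


@dataclass(frozen=True)
class RegionTrace:
    """Mean fluorescence per scan line over one spatial region."""

    values: np.ndarray
    times_ms: np.ndarray
    region_label: str = "full"
    region_roi: Roi | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        t = np.asarray(self.times_ms, dtype=np.float64)
        if v.ndim != 1 or t.ndim != 1 or v.shape != t.shape:
            raise ParameterError(
                f"values and times_ms must be matching 1-D vectors, got "
                f"{v.shape} and {t.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ParameterError("trace contains non-finite values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times_ms", t)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def ms_per_line(self) -> float:
        if len(self) < 2:
            raise InsufficientDataError("trace too short to infer ms_per_line")
        return float(self.times_ms[1] - self.times_ms[0])


@dataclass(frozen=True)
class PeakParams:
    """Peak detection controls.

    ``min_distance`` (the UI's "Peaks dist."): minimum separation between
    accepted peaks in lines; depends on acquisition rate and pacing
    frequency (see :data:`PEAKS_DIST_BY_HZ`). ``threshold_k``: the
    intensity threshold is ``mean(trace) + threshold_k * std(trace)``;
    the default ``k = 0`` is the plain trace average.
    """

    min_distance: int = 70
    threshold_k: float = 0.0

    def __post_init__(self) -> None:
        if self.min_distance < 1:
            raise ParameterError(
                f"min_distance must be >= 1, got {self.min_distance}"
            )


class Kinetics(NamedTuple):
    time_to_peak_ms: float
    time_to_half_ms: float
    max_upstroke: float


class TauFit(NamedTuple):
    tau_ms: float
    r_squared: float
    flagged: bool


@dataclass(frozen=True)
class TransientRecord:
    """One detected calcium transient with its kinetic parameters."""

    peak_index: int
    onset_index: int
    end_index: int
    peak_value: float
    baseline_value: float
    relative_amplitude: float
    time_to_peak_ms: float
    time_to_half_ms: float
    max_upstroke: float
    tau_ms: float  # NaN when the decay fit is undefined
    tau_flagged: bool


def region_trace(
    img: LineScanImage, roi: Roi | None = None, label: str = "full"
) -> RegionTrace:
    """Average the region's pixels at each line into a 1-D trace."""
    if roi is None:
        roi = img.full_roi()
    roi.validate_against(img)
    block = img.intensity[roi.line_start : roi.line_end, roi.pixel_start : roi.pixel_end]
    values = block.mean(axis=1)
    times = (np.arange(roi.line_start, roi.line_end) * img.ms_per_line)
    return RegionTrace(values=values, times_ms=times, region_label=label, region_roi=roi)


def detect_peaks(trace: RegionTrace, params: PeakParams) -> np.ndarray:
    """Locate transient peaks on a trace.

    Candidates are indices where the first-order difference changes sign
    from positive to non-positive (for a plateau top, its first sample).
    Candidates at or below ``mean + k*std`` of the trace are discarded,
    and the survivors are thinned greedily by descending height so that
    no two accepted peaks are closer than ``min_distance`` lines.

    Returns strictly increasing indices; an empty array when nothing
    qualifies (not an error).
    """
    v = trace.values
    n = len(v)
    if n < 3:
        raise InsufficientDataError(f"trace of length {n} is too short (< 3)")
    d = np.diff(v)
    rising = d[:-1] > 0
    falling = d[1:] <= 0
    candidates = np.nonzero(rising & falling)[0] + 1
    threshold = v.mean() + params.threshold_k * v.std()
    candidates = candidates[v[candidates] > threshold]
    if candidates.size == 0:
        return np.empty(0, dtype=np.intp)
    # greedy thinning: keep the tallest candidate, suppress neighbours
    order = np.lexsort((candidates, -v[candidates]))
    kept: list[int] = []
    for idx in candidates[order]:
        if all(abs(int(idx) - k) >= params.min_distance for k in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=np.intp)


def transient_bounds(
    trace: RegionTrace,
    peak_index: int,
    peaks: Sequence[int] | np.ndarray | None = None,
) -> tuple[int, int]:
    """Onset and end minima bracketing the transient at ``peak_index``.

    The onset is the minimum of the trace between the previous peak (or
    the trace start) and the peak; the end is the minimum between the
    peak and the next peak (or the trace end). Ties are broken toward the
    peak, so on a flat baseline the onset sits at the baseline/rise
    junction. Trace endpoints serve as fallbacks when no interior minimum
    exists.
    """
    v = trace.values
    n = len(v)
    if not 0 <= peak_index < n:
        raise BoundsError(f"peak_index {peak_index} outside trace of length {n}")
    if peak_index == 0:
        raise BoundsError("peak at trace start has no preceding samples")
    left, right = 0, n - 1
    if peaks is not None:
        arr = np.asarray(peaks, dtype=np.intp)
        before = arr[arr < peak_index]
        after = arr[arr > peak_index]
        if before.size:
            left = int(before.max())
        if after.size:
            right = int(after.min())
    pre = v[left : peak_index + 1]
    onset = left + int(np.flatnonzero(pre == pre.min()).max())
    post = v[peak_index : right + 1]
    end = peak_index + int(np.flatnonzero(post == post.min()).min())
    return onset, end


def relative_amplitude(trace: RegionTrace, peak_index: int, onset_index: int) -> float:
    """dF/F0: (peak - baseline) / baseline, baseline at the onset minimum."""
    baseline = float(trace.values[onset_index])
    if baseline <= 0:
        raise AmplitudeUndefinedError(
            f"baseline at index {onset_index} is {baseline}; dF/F0 needs a "
            "positive resting fluorescence (is the input background-subtracted?)"
        )
    return (float(trace.values[peak_index]) - baseline) / baseline


def kinetics(
    trace: RegionTrace,
    peak_index: int,
    onset_index: int,
    ms_per_line: float | None = None,
) -> Kinetics:
    """Time to peak, time to half amplitude (upstroke) and max +dF/dt.

    Time to half amplitude is the first upstroke crossing of
    ``baseline + amplitude/2``, linearly interpolated between the
    bracketing samples; it is therefore <= time to peak.
    """
    if not onset_index < peak_index:
        raise ParameterError(
            f"onset_index ({onset_index}) must precede peak_index ({peak_index})"
        )
    ms = trace.ms_per_line if ms_per_line is None else float(ms_per_line)
    v = trace.values
    baseline = v[onset_index]
    peak = v[peak_index]
    ttp = (peak_index - onset_index) * ms

    half = baseline + (peak - baseline) / 2.0
    upstroke = v[onset_index : peak_index + 1]
    above = np.nonzero(upstroke >= half)[0]
    h = int(above[0])
    if h == 0:
        t_half = 0.0
    else:
        lo, hi = upstroke[h - 1], upstroke[h]
        frac = 0.0 if hi == lo else (half - lo) / (hi - lo)
        t_half = (h - 1 + frac) * ms

    max_upstroke = float(np.diff(upstroke).max()) / ms
    return Kinetics(float(ttp), float(t_half), max_upstroke)


def decay_tau(
    trace: RegionTrace,
    peak_index: int,
    end_index: int,
    ms_per_line: float | None = None,
    *,
    floor: float | None = None,
    fit_fraction: float = 0.1,
    floor_guard: float = 0.0,
    quality_r2: float = 0.95,
) -> TauFit:
    """Mono-exponential decay constant of the segment peak -> next minimum.

    The segment is modelled as ``F(t) = F_floor + A * exp(-t / tau)`` and
    tau is obtained by linear least squares on ``log(F - F_floor)`` versus
    time. ``F_floor`` defaults to the segment's end value (the next
    minimum); when the decay is cut short — a transient truncated by the
    end of the recording — the end value overestimates the asymptote, so
    :func:`analyze_region` passes the diastolic baseline
    ``min(onset value, end value)`` instead. ``floor_guard`` lowers the
    floor by that fraction of the segment amplitude for callers who fit
    segments reaching the floor exactly.

    Only samples with ``F - F_floor`` above ``fit_fraction`` of the
    floor-subtracted peak enter the fit (the first ~2.3 tau of decay at
    the default 0.1): near the floor the log transform amplifies floor
    misestimation and noise, and the restriction also keeps every log
    argument positive.

    Raises :class:`TauUndefinedError` for flat or too-short segments; the
    returned ``flagged`` is True when the log-linear fit explains less
    than ``quality_r2`` of the variance (non-exponential decay shape).
    """
    if not end_index > peak_index + 2:
        raise TauUndefinedError(
            f"decay segment [{peak_index}, {end_index}] has fewer than 3 samples"
        )
    ms = trace.ms_per_line if ms_per_line is None else float(ms_per_line)
    seg = trace.values[peak_index : end_index + 1]
    amp = float(seg[0] - seg[-1])
    if amp <= 0:
        raise TauUndefinedError("decay segment is flat or rising; no decay to fit")
    # start at the first sample strictly below the maximum: the peak sample
    # sits at an unknown phase offset from the true decay onset (worst for a
    # flat-topped transient), which the fit intercept cannot absorb
    below = np.nonzero(seg < seg.max())[0]
    start = int(below[0]) if below.size else 1
    seg = seg[start:]
    if len(seg) < 3:
        raise TauUndefinedError("fewer than 3 samples after the transient maximum")
    if floor is None:
        floor = float(seg[-1])
    floor = floor - floor_guard * amp
    if floor >= seg[0]:
        raise TauUndefinedError("decay floor is not below the peak value")
    y = seg - floor
    cutoff = fit_fraction * (float(seg[0]) - floor)
    below = np.nonzero(y < cutoff)[0]
    stop = int(below[0]) if below.size else len(y)
    if stop < 3:
        raise TauUndefinedError("fewer than 3 usable samples above the decay floor")
    t = np.arange(stop) * ms
    logy = np.log(y[:stop])
    slope, intercept = np.polyfit(t, logy, 1)
    if slope >= 0:
        raise TauUndefinedError("decay segment has non-negative log-linear slope")
    resid = logy - (slope * t + intercept)
    ss_tot = float(((logy - logy.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    tau = -1.0 / slope
    if not math.isfinite(tau) or tau <= 0:
        raise TauUndefinedError("decay fit produced a non-positive tau")
    return TauFit(float(tau), r2, r2 < quality_r2)


def analyze_region(trace: RegionTrace, params: PeakParams) -> list[TransientRecord]:
    """Detect and characterise every transient on a trace.

    Transients whose decay cannot be fitted are reported with NaN tau and
    ``tau_flagged`` set, never dropped.
    """
    peaks = detect_peaks(trace, params)
    records: list[TransientRecord] = []
    for p in peaks:
        onset, end = transient_bounds(trace, int(p), peaks)
        amp = relative_amplitude(trace, int(p), onset)
        kin = kinetics(trace, int(p), onset)
        try:
            # diastolic baseline as decay asymptote: robust when the last
            # transient's decay is truncated by the end of the recording
            floor = float(min(trace.values[onset], trace.values[end]))
            fit = decay_tau(trace, int(p), end, floor=floor)
            tau_ms, tau_flagged = fit.tau_ms, fit.flagged
        except TauUndefinedError:
            tau_ms, tau_flagged = float("nan"), True
        records.append(
            TransientRecord(
                peak_index=int(p),
                onset_index=onset,
                end_index=end,
                peak_value=float(trace.values[p]),
                baseline_value=float(trace.values[onset]),
                relative_amplitude=amp,
                time_to_peak_ms=kin.time_to_peak_ms,
                time_to_half_ms=kin.time_to_half_ms,
                max_upstroke=kin.max_upstroke,
                tau_ms=tau_ms,
                tau_flagged=tau_flagged,
            )
        )
    return records
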