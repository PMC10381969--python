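"""Beat-to-beat alternans ratios and the subcellular discordance index.

The alternans ratio of two successive transients with magnitudes m1, m2 is

    AR = |m1 - m2| / max(m1, m2)

so AR = 0 means identical beats and AR -> 1 complete alternation. Global
AR is computed on the full-ROI trace using baseline-subtracted transient
amplitudes (peak minus onset minimum), which makes it invariant to
resting fluorescence and detector gain; raw peak intensities remain
available via ``magnitude="peak"``. Local (per-slice) ratios use the
maximal upstroke velocity +dF/dt of each transient, a measure of local
calcium release that is robust to the spatial displacement produced by
cell contraction.

The discordance index (DI) is the standard deviation of the local
alternans ratios: for each beat pair the sample SD of the ratios across
slices, averaged over pairs. Spatially uniform alternation (concordant)
gives DI near zero however strong the alternation; out-of-phase regions
and release heterogeneity inflate it. Slice upstrokes are aligned across
slices by the full-ROI beat times so that opposite-phase slices still
contribute to the same beat pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .transients import (
    PeakParams,
    RegionTrace,
    detect_peaks,
    kinetics,
    transient_bounds,
)

__all__ = [
    "PairRatio",
    "AlternansReport",
    "alternans_ratio",
    "global_alternans",
    "local_alternans",
    "discordance_index",
    "alternans_report",
]


@dataclass(frozen=True)
class PairRatio:
    """AR of one successive-beat pair."""

    pair_index: int
    first_value: float
    second_value: float
    ratio: float


@dataclass(frozen=True)
class AlternansReport:
    """Global and local alternans ratios plus discordance index for one image."""

    global_pairs: tuple[PairRatio, ...]
    global_ar: float
    local_ratios: np.ndarray  # (n_slices, n_pairs), NaN where unusable
    local_ar_summary: float
    discordance_index: float
    discordance_index_pooled: float
    n_slices: int
    n_pairs: int
    excluded_slices: tuple[tuple[int, str], ...] = field(default_factory=tuple)


def alternans_ratio(peak1: float, peak2: float) -> float:
    """AR = |peak1 - peak2| / max(peak1, peak2); symmetric, in [0, 1]."""
    if not (peak1 > 0 and peak2 > 0):
        raise ParameterError(
            f"alternans ratio needs positive magnitudes, got ({peak1}, {peak2})"
        )
    return abs(peak1 - peak2) / max(peak1, peak2)


def _peak_magnitudes(
    trace: RegionTrace, peaks: np.ndarray, magnitude: str
) -> np.ndarray:
    v = trace.values
    if magnitude == "peak":
        return v[peaks].astype(float)
    mags = np.empty(len(peaks), dtype=float)
    for i, p in enumerate(peaks):
        onset, _ = transient_bounds(trace, int(p), peaks)
        if magnitude == "amplitude":
            mags[i] = v[p] - v[onset]
        elif magnitude == "upstroke":
            mags[i] = kinetics(trace, int(p), onset).max_upstroke
        else:
            raise ParameterError(f"unknown magnitude mode {magnitude!r}")
    return mags


def global_alternans(
    trace: RegionTrace,
    peaks: np.ndarray,
    magnitude: str = "amplitude",
) -> tuple[list[PairRatio], float]:
    """Pairwise AR over the full-ROI trace and their mean (global AR)."""
    peaks = np.asarray(peaks, dtype=np.intp)
    if peaks.size < 2:
        raise InsufficientDataError(
            f"global alternans needs >= 2 peaks, found {peaks.size}"
        )
    mags = _peak_magnitudes(trace, peaks, magnitude)
    pairs = [
        PairRatio(i, float(mags[i]), float(mags[i + 1]), alternans_ratio(mags[i], mags[i + 1]))
        for i in range(len(mags) - 1)
    ]
    return pairs, float(np.mean([p.ratio for p in pairs]))


def local_alternans(
    slice_traces: list[RegionTrace],
    params: PeakParams,
    anchors: np.ndarray,
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Per-slice AR matrix on max +dF/dt, beats aligned to full-ROI peaks.

    ``anchors`` are the peak indices of the full-ROI trace; each slice's
    detected upstrokes are assigned to the nearest anchor within
    ``min_distance / 2`` lines, so opposite-phase slices pair the same
    physical beats. Returns a ``(n_slices, n_anchors - 1)`` matrix with
    NaN where a slice lacks a usable upstroke, plus the list of slices
    excluded entirely (index, reason).
    """
    anchors = np.asarray(anchors, dtype=np.intp)
    if anchors.size < 2:
        raise InsufficientDataError(
            f"local alternans needs >= 2 anchor beats, found {anchors.size}"
        )
    n_pairs = anchors.size - 1
    tol = max(1, params.min_distance // 2)
    ratios = np.full((len(slice_traces), n_pairs), np.nan)
    excluded: list[tuple[int, str]] = []
    for s, trace in enumerate(slice_traces):
        peaks = detect_peaks(trace, params)
        if peaks.size < 2:
            excluded.append((s, f"only {peaks.size} upstroke(s) detected"))
            continue
        mags = _peak_magnitudes(trace, peaks, "upstroke")
        per_anchor = np.full(anchors.size, np.nan)
        for a, anchor in enumerate(anchors):
            dist = np.abs(peaks - anchor)
            j = int(dist.argmin())
            if dist[j] <= tol:
                per_anchor[a] = mags[j]
        usable = 0
        for i in range(n_pairs):
            m1, m2 = per_anchor[i], per_anchor[i + 1]
            if np.isfinite(m1) and np.isfinite(m2) and m1 > 0 and m2 > 0:
                ratios[s, i] = alternans_ratio(m1, m2)
                usable += 1
        if usable == 0:
            excluded.append((s, "no upstroke pair aligned to the full-ROI beats"))
    return ratios, excluded


def discordance_index(local_ratios: np.ndarray, *, pooled: bool = False) -> float:
    """SD of the local alternans ratios.

    Default: sample SD (n-1) across slices for each beat pair, averaged
    over pairs — spatial discordance at each beat. ``pooled`` computes one
    sample SD over all finite ratios instead.
    """
    r = np.asarray(local_ratios, dtype=float)
    finite = np.isfinite(r)
    if finite.sum() < 2:
        raise InsufficientDataError("discordance index needs >= 2 local ratios")
    if pooled:
        return float(np.std(r[finite], ddof=1))
    r2d = np.atleast_2d(r)
    per_pair = []
    for col in range(r2d.shape[1]):
        vals = r2d[:, col][np.isfinite(r2d[:, col])]
        if vals.size >= 2:
            per_pair.append(np.std(vals, ddof=1))
    if not per_pair:
        raise InsufficientDataError(
            "no beat pair has >= 2 slices with finite local ratios"
        )
    return float(np.mean(per_pair))


def alternans_report(
    full_trace: RegionTrace,
    slice_traces: list[RegionTrace],
    params: PeakParams,
    magnitude: str = "amplitude",
) -> AlternansReport:
    """Full alternans/discordance analysis of one image."""
    anchors = detect_peaks(full_trace, params)
    if anchors.size < 2:
        raise InsufficientDataError(
            f"alternans analysis needs >= 2 full-ROI beats, found {anchors.size}"
        )
    pairs, global_ar = global_alternans(full_trace, anchors, magnitude)
    local, excluded = local_alternans(slice_traces, params, anchors)
    finite = np.isfinite(local)
    local_summary = float(local[finite].mean()) if finite.any() else float("nan")
    try:
        di = discordance_index(local)
    except InsufficientDataError:
        di = float("nan")
    try:
        di_pooled = discordance_index(local, pooled=True)
    except InsufficientDataError:
        di_pooled = float("nan")
    return AlternansReport(
        global_pairs=tuple(pairs),
        global_ar=global_ar,
        local_ratios=local,
        local_ar_summary=local_summary,
        discordance_index=di,
        discordance_index_pooled=di_pooled,
        n_slices=len(slice_traces),
        n_pairs=int(anchors.size - 1),
        excluded_slices=tuple(excluded),
    )
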