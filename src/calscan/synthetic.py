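"""Synthetic line-scan generator with closed-form ground truth.

Emulates the acquisition geometry of a Fluo-4 loaded cardiomyocyte imaged
in line-scan mode (by default 512 spatial pixels x 512 scan lines at
4.3 ms per line, ~0.2 um per pixel) under electrical pacing, producing
the four canonical phenotypes of beat-to-beat calcium handling:

``control``
    every beat identical across the cell;
``concordant_alternans``
    transient amplitude alternates large/small uniformly in space;
``discordant_alternans``
    spatial regions alternate in opposite phase. The alternation
    amplitude is modelled as a standing wave: a signed half-sine envelope
    per band with nodes at the band boundaries, the accepted picture of
    spatially discordant alternans (alternation vanishes at the node and
    is maximal mid-band);
``unsynchronized``
    disordered release: each band gets a random alternation phase, a
    random fractional alternation magnitude, and jittered beat times.

Each pixel's time course is multiplicative on the resting fluorescence,

    F(x, t) = F0 * (1 + sum_k  A * g_k(x) * s(t - t_k(x)))

where ``s`` is a unit transient (linear rise over ``rise_ms``, then
mono-exponential decay with ``tau_ms``) and ``g_k(x)`` implements the
beat/band amplitude pattern. Because transients are multiplicative, the
standard dF/F0 definition recovers the nominal amplitude exactly.

Ground truth is *realized*, not nominal: peak lines and per-beat dF/F0
are measured on the noiseless model traces, so overlap of a transient
with the previous beat's decaying tail is part of the truth rather than
an error term.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError
from .io import LineScanImage, write_tiff

__all__ = [
    "PATTERNS",
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "generate_linescan",
    "write_fixture",
]

PATTERNS = (
    "control",
    "concordant_alternans",
    "discordant_alternans",
    "unsynchronized",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generative line-scan model.

    ``alternation_factor`` is the fractional amplitude reduction of the
    small beat relative to the large beat (0 = none); under the
    multiplicative model the amplitude-based alternans ratio of a fully
    alternating region equals this factor. ``n_bands`` spatial bands
    carry the per-region phase for the discordant and unsynchronized
    patterns; ``phase_map`` assigns each band phase 0 or 1 (None =
    pattern default). ``node_width_px`` sets the spatial smoothing of the
    unsynchronized band profile. ``noise_scale`` is the Gaussian standard
    deviation in intensity units, or the photons-per-intensity-unit gain
    for Poisson noise.
    """

    n_lines: int = 512
    n_pixels: int = 512
    ms_per_line: float = 4.3
    um_per_pixel: float = 0.2
    baseline_f0: float = 100.0
    amplitude: float = 1.5
    rise_ms: float = 30.0
    peak_plateau_ms: float = 9.0
    tau_ms: float = 60.0
    pacing_hz: float = 3.0
    first_beat_ms: float = 60.0
    pattern: str = "control"
    alternation_factor: float = 0.0
    n_bands: int = 1
    phase_map: tuple[int, ...] | None = None
    node_width_px: float = 12.0
    jitter_sd_ms: float = 10.0
    noise_model: str = "gaussian"
    noise_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ParameterError(
                f"unknown pattern {self.pattern!r}; choose from {PATTERNS}"
            )
        for name in ("n_lines", "n_pixels", "n_bands"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        for name in (
            "ms_per_line",
            "um_per_pixel",
            "baseline_f0",
            "amplitude",
            "rise_ms",
            "tau_ms",
            "pacing_hz",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0.0 <= self.alternation_factor < 1.0:
            raise ParameterError(
                f"alternation_factor must be in [0, 1), got {self.alternation_factor}"
            )
        if self.peak_plateau_ms < 0:
            raise ParameterError("peak_plateau_ms must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ParameterError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ParameterError("noise_scale must be >= 0")
        if self.pattern == "discordant_alternans" and self.n_bands < 2:
            raise ParameterError("discordant_alternans needs n_bands >= 2")
        if self.phase_map is not None and len(self.phase_map) != self.n_bands:
            raise ParameterError(
                f"phase_map length {len(self.phase_map)} != n_bands {self.n_bands}"
            )
        period_ms = 1000.0 / self.pacing_hz
        if period_ms < 3.0 * self.rise_ms:
            raise ParameterError(
                f"pacing period {period_ms:.1f} ms must be >= 3x rise_ms "
                f"({self.rise_ms} ms)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Realized truth emitted alongside a synthetic image."""

    pattern: str
    alternation_factor: float
    tau_ms: float
    n_beats: int
    band_bounds: tuple[tuple[int, int], ...]
    band_profile: np.ndarray  # mean signed alternation profile per band
    beat_times_ms: np.ndarray  # (n_bands, n_beats) transient onset times
    band_peak_lines: np.ndarray  # (n_bands, n_beats) realized peak line
    band_amplitudes: np.ndarray  # (n_bands, n_beats) realized dF/F0
    full_peak_lines: np.ndarray  # (n_beats,) full-ROI realized peak line
    full_amplitudes: np.ndarray  # (n_beats,) full-ROI realized dF/F0


def default_spec(pattern: str, **overrides) -> SyntheticSpec:
    """Pattern presets: the study conditions each phenotype is generated under."""
    presets: dict[str, dict] = {
        "control": dict(alternation_factor=0.0, n_bands=1),
        "concordant_alternans": dict(alternation_factor=0.5, n_bands=1),
        "discordant_alternans": dict(alternation_factor=0.5, n_bands=2),
        "unsynchronized": dict(alternation_factor=0.5, n_bands=8),
    }
    if pattern not in presets:
        raise ParameterError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")
    kwargs = {**presets[pattern], **overrides, "pattern": pattern}
    return SyntheticSpec(**kwargs)


def _unit_transient(
    t_ms: np.ndarray, rise_ms: float, tau_ms: float, plateau_ms: float
) -> np.ndarray:
    """Linear rise to 1 over rise_ms, brief flat top, then exponential decay.

    The flat top (>= one scan line at the default calibration) stands in
    for the rounded peak of a real transient: it guarantees the sampled
    maximum equals the true amplitude regardless of where the scan-line
    grid falls relative to the peak, so sampling phase cannot masquerade
    as beat-to-beat alternation.
    """
    s = np.zeros_like(t_ms)
    rising = (t_ms >= 0) & (t_ms < rise_ms)
    s[rising] = t_ms[rising] / rise_ms
    top = (t_ms >= rise_ms) & (t_ms < rise_ms + plateau_ms)
    s[top] = 1.0
    decaying = t_ms >= rise_ms + plateau_ms
    s[decaying] = np.exp(-(t_ms[decaying] - rise_ms - plateau_ms) / tau_ms)
    return s


def _band_bounds(n_pixels: int, n_bands: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n_pixels, n_bands + 1).astype(int)
    return [(int(edges[b]), int(edges[b + 1])) for b in range(n_bands)]


def _alternation_profile(
    spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Signed per-pixel alternation envelope m(x) in [-1, 1].

    +1 alternates in the reference phase (odd beats small), -1 in the
    opposite phase, 0 no alternation at that position.
    """
    n = spec.n_pixels
    bounds = _band_bounds(n, spec.n_bands)
    if spec.pattern in ("control", "concordant_alternans"):
        return np.ones(n)
    if spec.pattern == "discordant_alternans":
        phases = spec.phase_map
        if phases is None:
            phases = tuple(b % 2 for b in range(spec.n_bands))
        m = np.zeros(n)
        for (lo, hi), ph in zip(bounds, phases):
            x = (np.arange(lo, hi) - lo + 0.5) / (hi - lo)
            sign = 1.0 if ph == 0 else -1.0
            m[lo:hi] = sign * np.sin(np.pi * x)  # standing-wave arch, nodes at edges
        return m
    # unsynchronized: random phase and random fractional magnitude per band
    phases = spec.phase_map
    if phases is None:
        phases = tuple(int(p) for p in rng.integers(0, 2, spec.n_bands))
    mags = rng.uniform(0.25, 0.75, spec.n_bands)
    m = np.zeros(n)
    for (lo, hi), ph, u in zip(bounds, phases, mags):
        m[lo:hi] = (1.0 if ph == 0 else -1.0) * u
    if spec.node_width_px > 0:
        m = gaussian_filter1d(m, spec.node_width_px, mode="nearest")
    return m


def generate_linescan(spec: SyntheticSpec) -> tuple[LineScanImage, GroundTruth]:
    """Render a synthetic line-scan image and its realized ground truth.

    Deterministic for a fixed spec (the seed covers every random draw).
    """
    rng = np.random.default_rng(spec.seed)
    n_lines, n_pixels = spec.n_lines, spec.n_pixels
    ms = spec.ms_per_line
    total_ms = n_lines * ms
    times = np.arange(n_lines) * ms

    f = spec.alternation_factor if spec.pattern != "control" else 0.0
    m = _alternation_profile(spec, rng)
    bounds = _band_bounds(n_pixels, spec.n_bands)

    period_ms = 1000.0 / spec.pacing_hz
    nominal = []
    k = 0
    while True:
        t_k = spec.first_beat_ms + k * period_ms
        if (t_k + spec.rise_ms + spec.peak_plateau_ms) / ms >= n_lines - 2:
            break
        nominal.append(t_k)
        k += 1
    if len(nominal) == 0:
        raise ParameterError("no transient peak falls inside the recording")
    n_beats = len(nominal)
    nominal = np.array(nominal)

    beat_times = np.tile(nominal, (spec.n_bands, 1))
    if spec.pattern == "unsynchronized" and spec.jitter_sd_ms > 0:
        jitter = rng.normal(0.0, spec.jitter_sd_ms, size=beat_times.shape)
        beat_times = beat_times + np.clip(jitter, -3 * spec.jitter_sd_ms, 3 * spec.jitter_sd_ms)
        beat_times = np.clip(
            beat_times, 0.0, (n_lines - 3) * ms - spec.rise_ms - spec.peak_plateau_ms
        )

    # D(x, t) = A * [(1 - f/2) S0_b(t) + (f/2) m(x) S1_b(t)]  (linear in m)
    noiseless = np.empty((n_lines, n_pixels))
    parity = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(n_beats)])
    for b, (lo, hi) in enumerate(bounds):
        s0 = np.zeros(n_lines)
        s1 = np.zeros(n_lines)
        for k in range(n_beats):
            s = _unit_transient(
                times - beat_times[b, k], spec.rise_ms, spec.tau_ms,
                spec.peak_plateau_ms,
            )
            s0 += s
            s1 += parity[k] * s
        d = spec.amplitude * (
            (1.0 - f / 2.0) * s0[:, None] + (f / 2.0) * m[None, lo:hi] * s1[:, None]
        )
        noiseless[:, lo:hi] = spec.baseline_f0 * (1.0 + d)

    truth = _measure_truth(spec, noiseless, bounds, beat_times, m)

    intensity = noiseless
    if spec.noise_scale > 0:
        if spec.noise_model == "gaussian":
            intensity = noiseless + rng.normal(0.0, spec.noise_scale, noiseless.shape)
        else:
            gain = spec.noise_scale
            intensity = rng.poisson(noiseless * gain).astype(np.float64) / gain
        intensity = np.clip(intensity, 0.0, None)

    img = LineScanImage(
        intensity=intensity,
        ms_per_line=ms,
        um_per_pixel=spec.um_per_pixel,
        source_name=f"synthetic:{spec.pattern}:seed{spec.seed}",
    )
    return img, truth


def _measure_truth(
    spec: SyntheticSpec,
    noiseless: np.ndarray,
    bounds: list[tuple[int, int]],
    beat_times: np.ndarray,
    m: np.ndarray,
) -> GroundTruth:
    """Peak lines and dF/F0 per beat, measured on noiseless model traces."""
    n_lines = spec.n_lines
    ms = spec.ms_per_line
    n_bands, n_beats = beat_times.shape

    def beat_measurements(trace: np.ndarray, onsets_ms: np.ndarray):
        peak_lines = np.empty(len(onsets_ms), dtype=np.intp)
        amplitudes = np.empty(len(onsets_ms))
        for k, t_k in enumerate(onsets_ms):
            lo = int(np.floor(t_k / ms))
            hi = min(
                n_lines - 1,
                int(np.ceil((t_k + 2.0 * spec.rise_ms + spec.peak_plateau_ms) / ms)),
            )
            window = trace[lo : hi + 1]
            peak_lines[k] = lo + int(window.argmax())
            onset_val = trace[lo]
            amplitudes[k] = (window.max() - onset_val) / onset_val
        return peak_lines, amplitudes

    band_peaks = np.empty((n_bands, n_beats), dtype=np.intp)
    band_amps = np.empty((n_bands, n_beats))
    band_profile = np.empty(n_bands)
    for b, (lo, hi) in enumerate(bounds):
        trace = noiseless[:, lo:hi].mean(axis=1)
        band_peaks[b], band_amps[b] = beat_measurements(trace, beat_times[b])
        band_profile[b] = m[lo:hi].mean()

    full_trace = noiseless.mean(axis=1)
    full_peaks, full_amps = beat_measurements(full_trace, beat_times.mean(axis=0))

    return GroundTruth(
        pattern=spec.pattern,
        alternation_factor=spec.alternation_factor if spec.pattern != "control" else 0.0,
        tau_ms=spec.tau_ms,
        n_beats=n_beats,
        band_bounds=tuple(bounds),
        band_profile=band_profile,
        beat_times_ms=beat_times,
        band_peak_lines=band_peaks,
        band_amplitudes=band_amps,
        full_peak_lines=full_peaks,
        full_amplitudes=full_amps,
    )


def write_fixture(
    img: LineScanImage,
    truth: GroundTruth,
    spec: SyntheticSpec,
    outdir: str | os.PathLike,
    stem: str = "synthetic",
) -> dict[str, str]:
    """Write TIFF + ground-truth CSV + spec JSON as a reproducibility record.

    The truth CSV has one row per (band, beat). Returns the written paths.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    tiff_path = os.path.join(outdir, f"{stem}.tif")
    write_tiff(img, tiff_path)

    truth_path = os.path.join(outdir, f"{stem}_truth.csv")
    with open(truth_path, "w", newline="") as fh:
        fh.write(
            "band,beat,band_start,band_end,onset_time_ms,peak_line,"
            "amplitude_dff0,tau_ms\n"
        )
        for b, (lo, hi) in enumerate(truth.band_bounds):
            for k in range(truth.n_beats):
                fh.write(
                    f"{b},{k},{lo},{hi},{truth.beat_times_ms[b, k]:.6g},"
                    f"{truth.band_peak_lines[b, k]},"
                    f"{truth.band_amplitudes[b, k]:.6g},{truth.tau_ms:.6g}\n"
                )

    spec_path = os.path.join(outdir, f"{stem}_spec.json")
    with open(spec_path, "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"tiff": tiff_path, "truth": truth_path, "spec": spec_path}
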