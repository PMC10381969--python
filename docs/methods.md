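# Methods

## Data model and coordinate conventions

A line-scan recording is held as a `LineScanImage`: a 2-D raster of
non-negative fluorescence intensities indexed `(line, pixel)` with rows
as scan lines (time) and columns as spatial positions. The temporal
calibration `ms_per_line` (> 0) maps line *t* to *t* · `ms_per_line` ms
(line 0 ↦ 0 ms); the optional spatial calibration `um_per_pixel`
(default 1) is used only to convert physical slice widths to pixels.
All intervals are 0-based and half-open; intensities are kept in native
units — nothing is rescaled at load time, and normalisation to baseline
happens only inside the amplitude computation. Multi-channel images are
reduced to scalar intensity at load (channel mean by default). Images
stored space × time can be transposed at load (`--transpose`).

The 16-bit TIFF writer is the only place intensities are quantized;
in-memory analysis of generated data runs on the unquantized raster, so
algorithmic error can be separated from quantization error.

## Preprocessing

**Bilateral smoothing** (optional, off by default). Each pixel is
replaced by the weighted mean of its circular neighbourhood of diameter
`kernel_size`, with Gaussian weights in both spatial distance (scale
`sigma`, pixels) and intensity difference (scale `sigma`, intensity
units). A single user-facing sigma drives both terms, matching the
single control of the original interface; advanced callers can set
`sigma_spatial` / `sigma_range` separately. `kernel_size = 0` or
`sigma = 0` is an exact no-op. Because the range sigma is in native
intensity units, 8-bit and 16-bit inputs need very different values.
The output is a convex combination of inputs, so it always stays within
the input min–max envelope. Smoothing is applied after cropping (less
work, no contamination from outside the ROI); `smooth_before_crop`
restores the other order.

**Slicing.** The ROI is tiled left-to-right into contiguous slices of a
fixed pixel width, each spanning the ROI's full time extent. The
physiologically motivated default is 2 µm — the spacing of RyR2 release
clusters, which can fire independently. A narrower last slice is kept
and flagged (its trace averages fewer pixels and is noisier); dropping
it silently would bias edge-of-cell statistics, but `drop_partial` is
available.

## Transient detection and kinetics

The mean intensity of the region's pixels at each line gives the
fluorescence-vs-time trace. Peak candidates are the indices where the
first-order difference changes sign from positive to non-positive; a
plateau top resolves to its first sample. Candidates at or below
`mean + k·SD` of the trace are discarded (default k = 0, the plain
trace average — which makes detection invariant to adding a constant to
the trace), and survivors are thinned greedily by descending height so
that no two accepted peaks are closer than `min_distance` lines. The
distance presets per pacing frequency (1 Hz: 200, 3 Hz: 70, 4 Hz: 50,
5 Hz: 40 lines at 4.3 ms/line) are offered as a convenience table, not
enforced.

For each peak, the transient's onset and end are the minima of the trace
between the neighbouring peaks (or the trace ends), with ties broken
toward the peak so that on a flat baseline the onset sits at the
baseline/rise junction. Taking the minimum of the inter-beat window —
rather than walking outward until the first uptick — makes the bounds
robust to noise during the slow late decay. From these:

* **ΔF/F₀** = (F_peak − F_onset)/F_onset. The baseline is per-transient
  (the preceding minimum), not a global trace minimum, because
  amplitudes are reported per transient. A non-positive baseline raises
  an error (it signals background-subtracted or miscalibrated input).
* **Time to peak** = (peak − onset) lines × `ms_per_line`.
* **Time to half amplitude** is measured on the upstroke: the first
  crossing of baseline + amplitude/2, linearly interpolated between the
  bracketing samples; by construction ≤ time to peak. (Rise-to-half,
  not decay-to-half.)
* **+dF/dt max** = the largest forward difference on the upstroke
  divided by `ms_per_line`; no additional derivative smoothing.

**Decay constant.** The segment from the peak to the next minimum is
modelled as F(t) = F_floor + A·e^(−t/τ) and fitted by linear least
squares on log(F − F_floor) versus time. Three numerical choices matter:

1. *Fit start.* The fit begins at the first sample strictly below the
   segment maximum. The peak sample sits at an unknown phase offset
   from the true decay onset (and may be part of a flat or rounded
   top); starting one sample later lets the intercept absorb the offset
   and leaves the slope — hence τ — unbiased.
2. *Floor.* Within `analyze_region` the floor is the diastolic baseline
   min(onset value, end value). For a transient truncated by the end of
   the recording the end value can sit far above the true asymptote,
   which would bend the log-linearised decay; the preceding diastolic
   minimum is then the better asymptote estimate. Stand-alone callers
   can pass any floor; the default is the segment end value.
3. *Fit range.* Only samples with F − F_floor ≥ 10 % of the
   floor-subtracted peak enter the fit (≈ the first 2.3 τ of decay).
   Near the floor the log transform amplifies floor misestimation and
   noise far beyond their effect on the fitted slope; the cutoff also
   guarantees positive log arguments, making an additive floor guard
   unnecessary (one is still available via `floor_guard`).

Segments that are flat, rising, or shorter than three usable samples
yield "τ undefined"; the transient is reported with missing τ rather
than dropped. An R² of the log-linear fit below 0.95 flags
non-exponential decay.

All reported times scale linearly with `ms_per_line` (calibration
equivariance), which the acceptance suite checks exactly.

## Alternans ratios and discordance index

For successive transient magnitudes the alternans ratio is
AR = |m₁ − m₂| / max(m₁, m₂): symmetric, scale-invariant, 0 iff the
magnitudes are equal, and ≤ 1 for positive inputs.

**Global AR** uses the full-ROI trace, one ratio per successive-peak
pair, summarised by the arithmetic mean. The default magnitude is the
baseline-subtracted transient amplitude (peak − onset minimum): this
makes the ratio invariant to resting fluorescence and detector offset,
so that under a multiplicative transient model the AR of a fully
alternating region equals the alternation fraction itself. Raw peak
intensities are available via `magnitude="peak"`; they fold the
baseline into both numerator and denominator and systematically
understate alternation by a factor ΔF/F₀ / (1 + ΔF/F₀).

**Local AR** is computed per spatial slice on the maximal upstroke
velocity +dF/dt of each transient — a measure of local release
magnitude that is insensitive to the spatial displacement of the local
signal produced by cell contraction. Because discordant regions
alternate out of phase, slices cannot be paired independently: each
slice's detected upstrokes are aligned to the full-ROI peak times
(nearest anchor within `min_distance`/2 lines), so every slice
contributes to the same physical beat pair. Slices with fewer than two
usable upstrokes are excluded from the index and listed with a reason.

**Discordance index.** DI is the standard deviation of the local
alternans ratios. The SD is taken across slices for each beat pair —
the spatial dispersion of alternation at that beat, which is the
phenomenon the index names — and averaged over pairs; sample SD (n − 1)
is used throughout. A pooled variant (one SD over all slice × pair
ratios) is available via `di_pooled`. DI is invariant under relabelling
of slices and zero when all slices agree exactly.

## Synthetic line-scan generator

The generator is the package's test bed and stands in for original
microscopy data. Each pixel's time course is multiplicative on the
resting fluorescence,

    F(x, t) = F₀ · (1 + Σₖ A · gₖ(x) · s(t − tₖ(x))),

with a unit transient s composed of a linear rise (default 30 ms), a
brief flat top (9 ms, ≈ 2 scan lines), and a mono-exponential decay
(default τ = 60 ms). The flat top stands in for the rounded peak of a
real transient: with a sharp corner, the sampled maximum depends on
where the scan-line grid falls relative to the peak, and at a pacing
period that is a non-integer number of lines this sampling phase
alternates beat-to-beat and masquerades as alternans; a top at least
one line wide removes the artifact. Multiplicative transients mean the
printed ΔF/F₀ definition recovers the nominal amplitude exactly.

Defaults mimic the acquisition geometry the indices were designed for:
512 pixels × 512 lines, 4.3 ms/line, 0.2 µm/pixel, F₀ = 100, ΔF/F₀
= 1.5, 3 Hz pacing (first beat at 60 ms), Gaussian noise with sd 3
intensity units (Poisson shot noise optional). Beat-to-beat patterns are
driven by a signed spatial alternation envelope m(x) ∈ [−1, 1] and an
alternation factor a (default 0.5 for the alternans phenotypes); beat k
of a pixel with envelope m carries the amplitude multiplier
1 − a·(1 − m·(−1)ᵏ)/2, so m = +1 and m = −1 alternate in opposite phase
and m = 0 does not alternate.

* **control** — m ≡ 1, a = 0: every beat identical.
* **concordant alternans** — m ≡ 1: uniform large/small alternation;
  the amplitude-based AR equals a by construction.
* **discordant alternans** — m is a standing wave: a signed half-sine
  arch per band (default 2 bands) with nodes at the band boundaries.
  This is the accepted spatial picture of discordant alternans: the
  alternation amplitude passes through zero at the nodal line and is
  maximal mid-band. A piecewise-constant ±1 profile would give every
  slice the same |alternation| and hence an unrealistically *low*
  spatial SD; the standing wave produces both the phase cancellation in
  the whole-cell trace and the across-slice dispersion that the
  discordance index measures.
* **unsynchronized** — disordered release, the "less ordered and less
  pronounced" phenotype: each of (default) 8 bands receives a random
  phase, a random alternation magnitude uniform in [0.25, 0.75] · a,
  and per-beat timing jitter (Gaussian, sd 10 ms); the signed profile
  is smoothed over ≈ 12 px so band transitions are not step edges.
  Local ARs end up above control but below the clear-alternans
  phenotypes, with intermediate spatial dispersion.

Ground truth is *realized*, not nominal: peak lines and per-beat ΔF/F₀
are measured on the noiseless per-band and full-ROI model traces, so
overlap with the previous beat's decaying tail is part of the truth
rather than an error term. τ is exact by construction (superposed tails
share the decay constant, and a sum of exponentials with one τ is again
exponential with that τ). Generation is deterministic given the spec:
for the deterministic patterns, distinct seeds differ only in the noise
realization.

What the generator does **not** emulate: motion artifacts from
contraction, photobleaching drift, depth-dependent signal loss,
Ca²⁺ sparks and waves, dye saturation, and structured detector noise.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every property of real microscopy
data; the validation of the indices against manually analysed recordings
is outside the scope of this package.

## Test and acceptance problem sizes

The acceptance checks run at the geometry above. τ recovery uses a
20/50/100/200 ms grid at 1 Hz pacing (distance preset 200): measuring a
200 ms decay constant needs an inter-beat window of several τ, which
1 Hz provides (≥ 5 τ) and 3 Hz does not (1.5 τ). Noisy recovery uses
Gaussian sd 15 (SNR 10 on the transient amplitude) over 20 seeds;
phenotype ordering (DI discordant > unsynchronized > control, global AR
concordant > control, and per-band AR exceeding the cancelled full-ROI
AR in the discordant case) is asserted over 20 seeds with one-sided
sign tests at p < 0.05. The acceptance script reports phenotype means
over 10 replicate images per pattern.

## Known limitations

* Under noise, the per-transient onset (an inter-beat minimum) can land
  anywhere within the flat diastolic segment, so time-to-peak is the
  noisiest reported kinetic parameter; amplitude is unaffected because
  the diastolic values differ only by noise.
* The mean-based threshold assumes transients occupy a minority of the
  trace; recordings that are mostly peak (very high pacing relative to
  τ) raise the mean and can suppress detection.
* τ is undefined (and reported missing) for transients with fewer than
  three decay samples above the fit cutoff — in practice, beats cut off
  by the end of the recording at small τ · `ms_per_line` ratios.
* Automatic phenotype labelling is intentionally out of scope: the
  package reports indices; classification thresholds are left to the
  user.
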