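# calscan

Calcium transient, alternans and discordance analysis for confocal
line-scan images of cardiomyocytes.

## What it does

In cardiomyocytes loaded with a Ca²⁺-sensitive dye such as Fluo-4,
confocal *line-scan* imaging repeatedly scans a single line along the
cell; stacking the scans gives a space × time fluorescence raster in
which every heartbeat appears as a calcium transient. `calscan` turns
such rasters (TIFF/PNG/JPG) into quantitative descriptions of Ca²⁺
handling:

* **per-transient kinetics** on the mean trace of a region of interest —
  relative amplitude ΔF/F₀ = (F_peak − F₀)/F₀, time to peak, time to
  half amplitude, maximal upstroke velocity +dF/dt, and the decay
  constant τ of a mono-exponential fit;
* **beat-to-beat alternans**: for successive transients with magnitudes
  m₁, m₂ the alternans ratio is

      AR = |m₁ − m₂| / max(m₁, m₂)

  (0 = identical beats, → 1 = complete alternation). The global AR is
  the mean pairwise AR of the full-ROI trace;
* **subcellular discordance**: the ROI is tiled into spatial slices
  (2 µm by default, matching the spacing of independently firing RyR2
  release clusters), local ARs are computed per slice on the maximal
  upstroke velocity +dF/dt (robust against motion of the local signal
  during contraction), and the **discordance index (DI)** is the
  standard deviation of the local ARs across slices. Spatially uniform
  alternation gives DI ≈ 0 regardless of AR; regions alternating out of
  phase inflate DI while their opposite phases cancel in the global AR.

Peaks are found from the first-order difference of the trace (sign
change from rising to non-rising), thresholded at the trace mean and
thinned by a minimum peak distance that depends on pacing frequency
(200 lines at 1 Hz, 70 at 3 Hz, 50 at 4 Hz, 40 at 5 Hz for 4.3 ms/line
acquisitions). An optional bilateral filter smooths the raster without
blurring the transient upstrokes.

Because no public line-scan data set accompanies the method, the package
ships a first-class synthetic generator (`calscan.synthetic`) that
renders calibrated 512 × 512 rasters at 4.3 ms/line for four phenotypes —
control, concordant alternans, subcellular discordant alternans and
unsynchronized Ca²⁺ release — with realized ground truth (beat times,
per-beat amplitudes, τ, band layout) for every image.

It is aimed at cardiovascular researchers quantifying impaired Ca²⁺
cycling (alternans, discordance, dyssynchrony) from confocal microscopy,
and at method developers who need a tested reference implementation of
these indices.

## Worked example

Generate a synthetic discordant-alternans image and analyze it with 2 µm
slices:

```
$ calscan synth --pattern discordant_alternans --seed 7 --out images
wrote images/discordant_alternans.tif (7 beats, pattern=discordant_alternans)

$ calscan analyze images/discordant_alternans.tif \
      --slice-width-um 2 --um-per-pixel 0.2 --peaks-dist 70 --out results
analyzed 1/1 image(s); summary: results/summary.csv
                   image  n_peaks  mean_rel_amplitude  mean_tau_ms  global_ar  discordance_index
discordant_alternans.tif        7            1.117382    59.228822   0.003312             0.1445
```

Reading the numbers: 7 transients were detected; the mean ΔF/F₀ of
≈ 1.12 sits between the generator's alternating large (1.5) and small
(0.75) beats; τ ≈ 59 ms recovers the generated 60 ms decay. The global
AR is ≈ 0 even though both cell halves alternate strongly — they do so
in opposite phase, so their alternation cancels in the full-cell trace —
while the discordance index of 0.14 exposes exactly this spatial
heterogeneity. A concordant image from the same generator yields the
mirror image (global AR ≈ 0.5, DI ≈ 0.04).

`results/` also contains per-transient tables for the full cell and for
every slice, the per-pair global/local AR table, and a JSON run log that
records the configuration and package version needed to reproduce the
run. All times are in ms and amplitudes dimensionless; each CSV carries
a schema comment line.

The same analysis is available as a library:

```python
import calscan as cs

spec = cs.default_spec("discordant_alternans", seed=7)
img, truth = cs.generate_linescan(spec)
res = cs.analyze_image(img, cs.AnalysisConfig(slice_width_um=2.0,
                                              um_per_pixel=spec.um_per_pixel,
                                              ms_per_line=spec.ms_per_line))
print(res.summary["discordance_index"])   # 0.1445...
```

## Documentation

`docs/methods.md` describes the model, the estimators, the synthetic
data generator and its limitations, and all numerical choices.
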