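# Methods

## Scope and model of the data

`csfpulse` analyzes magnitude EPI time series sampled fast enough (TR
51–155 ms) that cardiac (~1.2 Hz), respiratory (~0.3 Hz) and first
cardiac-harmonic (~2.4 Hz) pulsations of the CSF and brain tissue are
resolved below the Nyquist frequency 1/(2·TR).  The package consumes
*preprocessed* data: denoising, distortion/bias correction, skull stripping
and segmentation are upstream concerns, and the label map (CSF / cortical
grey matter / cerebral white matter) is taken as given.

A voxel's time series x(t), t = 0..T−1, is modelled as a constant baseline
plus narrowband physiological oscillations, slow drift, and noise that is
Rician in magnitude images.  All analysis happens on one-sided magnitude
spectra.

## Spectral conventions

* Frequency grid: Δf = 1/(T·TR), bins k·Δf for k = 0..⌊T/2⌋.  For 600
  volumes at TR 155 ms: Δf ≈ 0.0108 Hz, f_max ≈ 3.226 Hz.
* The temporal mean is removed per voxel before the FFT (the DC bin is
  exactly zero).  No window/taper is applied, so an on-grid sinusoid of
  amplitude A appears with magnitude exactly A at its bin (interior bins
  scaled 2/T; DC and Nyquist 1/T).  An optional linear detrend exists but
  is off by default.
* ROI spectra are arithmetic means of per-voxel *magnitudes* per frequency,
  never of complex coefficients — components with voxel-dependent phase
  (travelling pulsation fronts) would cancel in a complex average.
  A consequence worth knowing: a coherent component whose per-bin magnitude
  is far below the per-voxel noise floor is suppressed quadratically in the
  magnitude average (Rician small-signal bias), not linearly.
* Magnitude, not power, is the stored quantity; "3 dB" is interpreted in
  the amplitude convention (factor √2/2).  Band power maps can be switched
  to squared magnitudes with a flag.

## Peak identification

The six-stage algorithm operates per spectrum:

1. **Savitzky–Golay smoothing**, order 2, window 0.133 Hz — the width of
   the normal adult respiratory range (12–20 breaths/min).  The window is
   converted to an odd sample count via Δf (minimum 5, capped at the
   spectrum length); for very short TR (≤ 75 ms) the sample count is
   doubled, since those grids extend far beyond the physiological range.
2. **Lower envelope**: piecewise-linear interpolation through the strict
   local minima of the smoothed curve (plus the first and last analyzed
   bins), clipped to lie at or below the curve and floored at
   1e-12·max to stay positive.  The envelope models the acquisition's
   decreasing spectral floor.
3. **Adjusted spectrum**: smoothed/envelope − 1 (dimensionless, ≥ 0, zero
   at every envelope knot).  Scale-invariant: rescaling the raw spectrum
   leaves it unchanged.
4. **Primary peaks**: local maxima with height ≥ mean + sample std of the
   adjusted spectrum.
5. **Baseline**: a zone of total width 0.667 Hz — the 60–100 beats/min
   cardiac span — is excluded around each primary peak; mean and sample
   std of the remaining bins form the baseline.  (A flag switches the zone
   to half-width interpretation.)
6. **Final peaks**: local maxima with height ≥ baseline mean + std *and*
   topographic prominence ≥ 1.5 dB measured on the envelope-ratio curve
   20·log10(1 + adjusted) (equivalently a linear ratio of ≈1.188).

Numerical choices: all standard deviations use the sample (n−1) convention
(the published two-subject band std is only consistent with n−1); the DC
bin is excluded from every statistic and can never be a peak; flat-topped
plateaus count as one peak at their center bin with ties broken toward the
lower frequency.

The DC bin is also excluded from the *curve* stages: the demeaned DC value
(exactly zero) is a preprocessing artifact, and letting it into the
smoother's edge fit bends the smoothed curve into a spurious bump near
0.05–0.07 Hz.  Smoothing and envelope therefore run on bins 1.., with bin 0
carried as a duplicate of bin 1 for array alignment.

## Band biomarkers

A final peak becomes a band by walking outward on the adjusted spectrum to
the first crossing of √2/2 × peak height (linear interpolation between
bins).  If the grid edge is reached, or the curve climbs above the peak
height (an adjacent taller peak) before crossing, the band is cut at the
edge or the intervening valley and flagged `truncated` — truncated bands
are reported, not dropped.  The band's area is the trapezoidal integral of
the (dimensionless) adjusted curve over [f_lo, f_hi], hence in Hz.  A flag
allows measuring bands on the smoothed raw spectrum instead.

Bands from several subjects are grouped by single-linkage clustering of
center frequencies with a 0.2 Hz tolerance (chosen so that published
cardiac-band centers spanning 1.129–1.312 Hz form one group that stays
separate from the neighbouring 0.763–0.914 Hz band).  Note that single
linkage at 0.2 Hz would merge the published Band 1 (≤0.387 Hz) with
Band 2 (≥0.484 Hz); when reproducing published summaries the table's own
band assignment is used as the grouping.

## Spatial maps

Per band, the power map holds each voxel's mean spectral magnitude over the
band's grid bins.  The map is binarized at 75% of its peak value, smoothed
with a Gaussian of sigma 1.6 (voxel units; 3D by default, slice-wise 2D by
flag) and re-binarized at 0.5 — the symmetric choice, which preserves the
interior of large solid regions and deletes isolated speckles.

## Physiological comparison

ECG and respiration-belt traces are cropped to the scan window using the
scanner-trigger timestamp, spectrum-analyzed on their own grid
(Δf = 1/duration, restricted to ≤ 10 Hz for peak finding), and
peak-identified with the same six-stage algorithm.  MRI and physio bands
are compared in frequency-interval space (intersection plus Jaccard
fraction); no resampling onto the MRI grid is performed.

## The synthetic phantom

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

* **Geometry**: concentric ellipsoids — CSF core (baseline 1400 a.u.),
  white matter around it (700 a.u.), a grey-matter rim (900 a.u.) — on a
  zero background.  Regions are disjoint and the masks are part of the
  ground truth.
* **Pulsations**: components at 0.3/1.2/2.4 Hz (snapped to the FFT grid by
  default), with per-region amplitude fractions 0.015/0.008/0.004
  (respiratory), 0.030/0.010/0.004 (cardiac) and one third of cardiac for
  the harmonic (CSF/cGM/cWM) — CSF-dominant by design.  Each component is
  a narrowband process: a comb of on-grid sub-lines with Gaussian weights
  (linewidth 0.045–0.07 Hz, emulating breathing/heart-rate variability)
  and seeded random phases, shared across regions (one heart, one pair of
  lungs).  This puts the spectra in the regime real data occupy —
  adjusted-peak magnitudes of order 0.1–10 and 3 dB bandwidths near
  0.05–0.1 Hz.  A pure on-grid sinusoid would instead concentrate ~100×
  the noise floor into a single bin, a regime in which any
  polynomial smoother rings and envelope normalization degenerates;
  `linewidth_hz=0` remains available for such stress tests.
* **Drift**: linear, −0.05/−0.04/−0.03 a.u./s per region (fractions of a
  percent over the 93 s scan, typical of scanner drift).
* **Noise**: per-voxel colored noise with a 1/f^0.6 power spectrum
  (σ = 2 a.u.) gives the ROI spectra the decreasing acquisition-like lower
  envelope; Rician magnitude noise observed = √((S+ε₁)²+ε₂²) with
  σ = 2.5 a.u. adds the flat floor.  The defaults keep the per-bin
  component signal above the per-voxel floor in all three regions — the
  condition under which magnitude averaging preserves the CSF > cGM > cWM
  amplitude ordering through to detection.
* **Physio traces**: a respiratory sinusoid and an ECG-like train of 25 ms
  Gaussian pulses at the phantom's rates, sampled at 250 Hz with a 10 s
  pre-trigger segment and noise σ = 0.05.

Everything is deterministic given the seed.  What the phantom does *not*
emulate: k-space acquisition, coil sensitivities, B0 distortion, motion,
partial-volume mixing at region boundaries, spatially varying noise, or
BOLD fluctuations — so passing tests demonstrate correctness of the
spectral analysis chain under the stated signal model, not robustness to
every artifact of real scans.

## Validation problem sizes

Phantom recovery trials run on 20 seeded phantoms of 64×64×20 voxels ×
600 volumes (TR 155 ms): final CSF peaks within one bin of all three
component frequencies, cardiac-band magnitude ordering CSF > cGM > cWM,
and cardiac-band mask Dice ≥ 0.8 against the true CSF geometry.
Physiological-coupling trials use 20 phantoms of 32×32×12×600 (the ROI
spectra are averages, insensitive to volume; the time axis — and hence the
grid — is unchanged) and require a cardiac-band and a respiratory-band
MRI/physio overlap pair.

The "decreasing lower envelope" property of the generator is verified on a
signal-free phantom (the analog of a physical phantom scan): with
stochastic voxel noise the envelope knots carry sampling ripple of order
0.1%, so strict bin-by-bin decrease is not a meaningful requirement; the
test asserts strictly decreasing 0.25 Hz block means over 0.05–3 Hz
together with an overall floor drop.

## Known limitations

* Slabs acquired at different times are merged without phase alignment;
  only magnitude spectra are interpreted (consistent with per-voxel FFT
  magnitude being invariant to slab start times).
* No statistical significance testing of peaks beyond the height and
  prominence thresholds; no between-region inference.
* Band areas/bandwidths computed on the adjusted spectrum are in envelope
  units, not raw signal units; comparisons across acquisitions assume
  similar envelope shapes.
* Whole-spectrum magnitudes are arbitrary units; only ratios and
  frequencies transfer across scanners.
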