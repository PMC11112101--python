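# csfpulse

Spectral characterization of physiological brain and CSF pulsations in
ultrafast EPI time series.

## The problem

Cerebrospinal fluid (CSF) pulsates with the cardiac cycle (~1.2 Hz, with a
harmonic near 2.4 Hz) and with respiration (~0.3 Hz), and these pulsations
are thought to drive the clearance of metabolic waste from the brain.
With sufficiently fast echo-planar imaging (TR 51–155 ms per volume) those
rhythms sit below the Nyquist frequency 1/(2·TR) and modulate the EPI
magnitude signal directly, so they can be measured — per voxel, per region,
and across the whole brain — without contrast injection.  `csfpulse` is for
researchers who have such preprocessed 4D acquisitions (plus, optionally, a
CSF/grey/white segmentation and ECG/respiration-belt recordings) and want
frequency-resolved pulsatility biomarkers and their spatial maps.

## The method

For a series of T volumes sampled every TR seconds, each voxel is demeaned
and Fourier transformed onto the grid Δf = 1/(T·TR), k·Δf ≤ 1/(2·TR);
ROI spectra average per-voxel magnitudes per frequency.  Peaks are then
identified on an envelope-normalized spectrum:

1. Savitzky–Golay smoothing (order 2, window 0.133 Hz — the normal adult
   respiratory range of 12–20 breaths/min);
2. lower envelope: linear interpolation through the local minima of the
   smoothed curve (the acquisition's decreasing spectral floor);
3. adjusted spectrum A(f) = smoothed/envelope − 1;
4. primary peaks: local maxima with A ≥ mean(A) + std(A);
5. baseline mean/std over bins outside an exclusion zone of total width
   0.667 Hz (the 60–100 beats/min cardiac range) around each primary peak;
6. final peaks: local maxima above baseline mean + std with topographic
   prominence ≥ 1.5 dB on 20·log₁₀(1 + A).

Each final peak yields a band: the 3 dB edges where A first falls below
√2/2 of the peak height, the bandwidth f_hi − f_lo, and the area ∫A df
(Hz).  Band power maps (per-voxel mean magnitude over the band's bins) are
binarized at 75% of their peak, Gaussian-smoothed (σ = 1.6 voxels) and
re-binarized, localizing each rhythm anatomically.  Physiological traces
are trigger-aligned, spectrum-analyzed the same way, and compared with MRI
bands in frequency-interval space.

A seeded synthetic phantom (concentric CSF/white/grey ellipsoids,
narrowband pulsations at 0.3/1.2/2.4 Hz with CSF-dominant amplitudes,
drift, 1/f-colored noise and Rician magnitude noise, matched ECG and
respiration traces) makes the whole pipeline testable without scan data.
See `docs/methods.md` for the full model and parameter rationale.

## Worked example

```python
import csfpulse as cp

spec = cp.PhantomSpec(seed=7)                      # 64×64×20 voxels, 600 volumes, TR 155 ms
image, labels, truth = cp.make_phantom(spec)
spectra = cp.region_spectra(image, labels)         # csf, cgm, cwm, whole-brain
adj, peaks = cp.identify_peaks(spectra["csf"])
bands = cp.bands_from_peaks(adj, peaks, region="csf")
print(cp.bandmetrics.bands_to_frame(bands).round(3).to_string(index=False))
```

```
region subject  frequency_hz  magnitude_au  area_hz  bandwidth_hz  f_lo_hz  f_hi_hz  truncated
   csf                 0.301         6.718    0.444         0.074    0.266    0.339      False
   csf                 1.204        16.577    1.251         0.084    1.162    1.247      False
   csf                 2.398         3.193    0.295         0.103    2.346    2.450      False
```

The three detected CSF bands sit exactly on the generator's respiratory,
cardiac and harmonic frequencies (snapped to the 0.0108 Hz grid); the
magnitudes are envelope-relative peak heights and the bandwidths are the
3 dB widths in Hz.  The cardiac band's spatial mask recovers the true CSF
geometry:

```python
mask = cp.band_mask(image, bands[1])               # 75% binarize + σ=1.6 smooth
# mask.mask.sum() -> 3096 voxels, of 3392 true CSF voxels (Dice ≈ 0.95)
```

The same workflow runs from the shell:

```bash
csf-pulse simulate --seed 7 --out-dir sim/
csf-pulse run --in sim/phantom_epi.nii.gz --labels sim/phantom_labels.nii.gz \
              --tr 0.155 --out-dir out/
```

writing region spectra, per-stage curves, peak/band tables, band masks and
a reproducible run manifest.

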